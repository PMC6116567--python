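"""Synthetic block-averaged fNIRS fixtures for testing and recovery studies.

Fixtures are forward simulations of a registry scenario resampled to a
measurement rate with independent Gaussian noise per channel, the noise
standard deviation referenced to the peak |ΔHbO2| of the noise-free run so
a given ``noise_fraction`` means the same relative corruption in every
scenario.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import DomainBoundError
from .fitting import MeasuredTraces
from .model_core import ParameterSet
from .scenarios import Scenario, get_scenario, run_scenario

__all__ = ["NoiseSpec", "make_fixture", "make_recovery_suite", "read_manifest"]

_CHANNELS = ("dHbO2", "dHHb", "dHbT")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive-noise description for one synthetic measurement."""

    noise_fraction: float       # Gaussian σ as a fraction of peak |ΔHbO2|
    seed: int                   # generator seed; no hidden global state
    sampling_rate: float = 1.0  # Hz

    def __post_init__(self) -> None:
        if self.noise_fraction < 0:
            raise DomainBoundError("noise_fraction must be >= 0")
        if not self.sampling_rate > 0:
            raise DomainBoundError("sampling_rate must be > 0")


def make_fixture(
    scenario: str | Scenario,
    noise: NoiseSpec,
    *,
    params: ParameterSet | None = None,
    sigma_per_channel: dict[str, float] | None = None,
    trajectory=None,
) -> MeasuredTraces:
    """Simulate a scenario and corrupt it into a synthetic measurement.

    The noise-free Δ-signals are resampled to ``noise.sampling_rate`` by
    linear interpolation; independent Gaussian noise with
    σ = noise_fraction × peak |ΔHbO2| (overridable per channel) is added to
    each channel.  Deterministic for a given seed.  A precomputed clean
    ``trajectory`` of the same scenario may be supplied to skip the forward
    simulation (useful for many-replicate noise studies).
    """
    traj = trajectory if trajectory is not None else run_scenario(scenario, params=params)
    t = np.arange(traj.time[0], traj.time[-1] + 1e-9, 1.0 / noise.sampling_rate)
    clean = {name: np.interp(t, traj.time, getattr(traj, name)) for name in _CHANNELS}
    sigma0 = noise.noise_fraction * float(np.max(np.abs(traj.dHbO2)))
    rng = np.random.default_rng(noise.seed)
    noisy = {}
    for name in _CHANNELS:
        sigma = (sigma_per_channel or {}).get(name, sigma0)
        noisy[name] = clean[name] + rng.normal(0.0, 1.0, size=t.shape) * sigma
    return MeasuredTraces(time=t, **noisy)


def make_recovery_suite(
    alphas: Sequence[float],
    betas: Sequence[float],
    noise_levels: Sequence[float],
    seeds: Sequence[int],
    out_dir: str | Path,
    *,
    template: str | Scenario = "roche_labarbe",
    sampling_rate: float = 1.0,
) -> Path:
    """Write a grid of parameter-recovery fixtures plus a JSON manifest.

    One fixture CSV is produced per (alpha, beta, noise level, seed)
    combination, all generated from ``template`` with its demand/pressure
    amplitudes replaced.  The manifest records the true amplitudes and
    generation settings so recovery experiments can score themselves.

    Returns the manifest path.
    """
    sc = get_scenario(template) if isinstance(template, str) else template
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for alpha in alphas:
        for beta in betas:
            variant = sc.with_amplitudes(alpha=float(alpha), beta=float(beta))
            clean = run_scenario(variant)  # one simulation per amplitude pair
            for noise_fraction in noise_levels:
                for seed in seeds:
                    spec = NoiseSpec(
                        noise_fraction=float(noise_fraction),
                        seed=int(seed),
                        sampling_rate=sampling_rate,
                    )
                    traces = make_fixture(variant, spec, trajectory=clean)
                    fname = (
                        f"fix_a{alpha:g}_b{beta:g}_n{noise_fraction:g}_s{seed}.csv"
                    )
                    traces.to_csv(out_dir / fname)
                    entries.append(
                        {
                            "file": fname,
                            "scenario": sc.name,
                            "alpha": float(alpha),
                            "beta": float(beta),
                            "gamma": sc.amplitudes.gamma,
                            "noise_fraction": float(noise_fraction),
                            "seed": int(seed),
                            "sampling_rate": sampling_rate,
                        }
                    )
    manifest = {
        "template": sc.name,
        "sampling_rate": sampling_rate,
        "fixtures": entries,
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest_path


def read_manifest(path: str | Path) -> dict:
    """Load a recovery-suite manifest written by :func:`make_recovery_suite`."""
    return json.loads(Path(path).read_text())
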