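"""Registry of the published stimulus simulations and the autoregulation sweep.

Six named scenarios are provided, one per reported simulation:

``kozberg_bp_rise``
    Somatosensory stimulus in rats with a blood-pressure rise: demand
    alpha = 2 together with a +1.5 mmHg pressure excursion.  (The printed
    pressure formula subtracts beta·HRF, so the rise is encoded as
    beta = −1.5; the study describes an unambiguous pressure *increase*.)
``kozberg_no_hyperemia``
    Rats without functional hyperemia: a 1 % direct radius reduction
    (gamma = 0.01) with a small pressure decrease (beta = 0.18) and no
    demand increase.
``roche_labarbe``
    Somatosensory stimulus in preterm neonates: demand alpha = 0.5.
``usz_neonate1``
    Visual stimulus, subject 1: demand alpha = 0.7.
``usz_neonate2``
    Visual stimulus, subject 2: demand alpha = 0.7 with CBF clamped at its
    normal value.
``usz_neonate2_bp``
    As ``usz_neonate2`` plus a 7 mmHg pressure decrease (beta = 7).

The rat scenarios run on the preterm human preset: the animals are
age-equivalent to human newborns and the model is parameterised for the
human neonate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ScenarioLookupError, SteadyStateError
from .model_core import (
    InstantaneousInputs,
    ParameterSet,
    baseline_inputs,
    derived_quantities,
    load_preset,
    steady_state,
)
from .simulate import Trajectory, run
from .stimulus import HRFSpec, StimulusAmplitudes, build_timeline

__all__ = ["Scenario", "registry", "get_scenario", "run_scenario", "autoregulation_curve", "plateau_width"]

_DEFAULT_DT = 0.1
_DEFAULT_DURATION = 60.0


@dataclass(frozen=True)
class Scenario:
    """A named, runnable stimulus experiment."""

    name: str
    preset: str
    amplitudes: StimulusAmplitudes
    hrf: HRFSpec
    clamp_cbf: bool = False
    duration: float = _DEFAULT_DURATION
    dt: float = _DEFAULT_DT

    def time_grid(self) -> np.ndarray:
        n = int(round(self.duration / self.dt)) + 1
        return np.linspace(0.0, self.duration, n)

    def with_amplitudes(self, **changes) -> "Scenario":
        return replace(self, amplitudes=self.amplitudes.replace(**changes))


def _hrf(duration: float) -> HRFSpec:
    return HRFSpec(stimulus_onset=10.0, stimulus_duration=duration)


def registry() -> list[Scenario]:
    """All built-in scenarios with their published stimulus amplitudes."""
    return [
        Scenario(
            name="kozberg_bp_rise",
            preset="preterm",
            amplitudes=StimulusAmplitudes(alpha=2.0, beta=-1.5),
            hrf=_hrf(10.0),
        ),
        Scenario(
            name="kozberg_no_hyperemia",
            preset="preterm",
            amplitudes=StimulusAmplitudes(alpha=0.0, beta=0.18, gamma=0.01),
            hrf=_hrf(10.0),
        ),
        Scenario(
            name="roche_labarbe",
            preset="preterm",
            amplitudes=StimulusAmplitudes(alpha=0.5),
            hrf=_hrf(10.0),
        ),
        Scenario(
            name="usz_neonate1",
            preset="neonate1",
            amplitudes=StimulusAmplitudes(alpha=0.7),
            hrf=_hrf(20.0),
        ),
        Scenario(
            name="usz_neonate2",
            preset="neonate2",
            amplitudes=StimulusAmplitudes(alpha=0.7),
            hrf=_hrf(20.0),
            clamp_cbf=True,
        ),
        Scenario(
            name="usz_neonate2_bp",
            preset="neonate2",
            amplitudes=StimulusAmplitudes(alpha=0.7, beta=7.0),
            hrf=_hrf(20.0),
            clamp_cbf=True,
        ),
    ]


def get_scenario(name: str) -> Scenario:
    for sc in registry():
        if sc.name == name:
            return sc
    names = ", ".join(sc.name for sc in registry())
    raise ScenarioLookupError(f"unknown scenario {name!r}; valid names: {names}")


def run_scenario(
    scenario: str | Scenario,
    params: ParameterSet | None = None,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Simulate one scenario: load preset, build the timeline, integrate.

    ``params`` overrides the scenario's preset (it must be calibrated).
    """
    sc = get_scenario(scenario) if isinstance(scenario, str) else scenario
    if params is None:
        params = load_preset(sc.preset)
    timeline = build_timeline(
        sc.amplitudes, sc.hrf, params, sc.time_grid(), clamp_cbf=sc.clamp_cbf
    )
    meta = {
        "scenario": sc.name,
        "preset": sc.preset,
        "alpha": sc.amplitudes.alpha,
        "beta": sc.amplitudes.beta,
        "gamma": sc.amplitudes.gamma,
        "cbf_clamped": sc.clamp_cbf,
    }
    return run(params, timeline, rtol=rtol, atol=atol, metadata=meta)


def autoregulation_curve(
    params: ParameterSet, pressures: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Steady-state CBF at each arterial pressure in the grid.

    Returns the (pressure, CBF) arrays.  The curve passes through
    (P_a_n, CBF_n) by construction of the calibration.
    """
    pressures = np.asarray(pressures, dtype=float)
    cbf = np.empty_like(pressures)
    for i, p in enumerate(pressures):
        inputs = InstantaneousInputs(
            P_a=float(p), SaO2=params.SaO2_n, PaCO2=params.PaCO2_n
        )
        try:
            state = steady_state(params, inputs)
        except SteadyStateError as exc:
            raise SteadyStateError(
                f"autoregulation sweep failed at P_a = {p:.2f} mmHg: {exc}"
            ) from exc
        cbf[i] = derived_quantities(state, inputs, params).CBF
    return pressures, cbf


def plateau_width(
    params: ParameterSet,
    *,
    span: float = 0.6,
    dp: float = 0.25,
    slope_tol: float = 0.01,
) -> float:
    """Width (mmHg) of the autoregulation plateau around the operating point.

    The plateau is the contiguous pressure interval containing P_a_n where
    the normalised slope |d(CBF/CBF_n)/dP_a| stays below ``slope_tol`` per
    mmHg, measured on a grid spanning ±``span``·P_a_n.
    """
    p0 = params.P_a_n
    grid = np.arange(p0 * (1.0 - span), p0 * (1.0 + span) + dp / 2, dp)
    _, cbf = autoregulation_curve(params, grid)
    slope = np.gradient(cbf / params.CBF_n, grid)
    ok = np.abs(slope) < slope_tol
    i0 = int(np.argmin(np.abs(grid - p0)))
    if not ok[i0]:
        return 0.0
    lo = i0
    while lo > 0 and ok[lo - 1]:
        lo -= 1
    hi = i0
    while hi < len(grid) - 1 and ok[hi + 1]:
        hi += 1
    return float(grid[hi] - grid[lo])
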