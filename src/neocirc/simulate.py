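"""Time integration of the model over an input timeline.

Produces a :class:`Trajectory` holding states, derived observables and the
fNIRS-style Δ-signals (changes from the pre-stimulus baseline, μM) together
with relative CBF / CMRO2 / CBV traces.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import AlignmentError, SimulationError
from .model_core import InstantaneousInputs, ParameterSet, steady_state
from .stimulus import InputTimeline

__all__ = ["Trajectory", "run", "block_average"]

#: pre-stimulus window (s) whose mean defines the Δ-signal zero
BASELINE_WINDOW = 10.0

_CSV_COLUMNS = [
    "time", "dHbO2", "dHHb", "dHbT", "dOxCCO", "rCBF", "rCMRO2", "rCBV", "Pa", "u",
]


@dataclass
class Trajectory:
    """Time-indexed record of model states, observables and Δ-signals."""

    time: np.ndarray
    mu: np.ndarray
    O2t: np.ndarray
    a: np.ndarray
    r: np.ndarray
    CBF: np.ndarray
    CMRO2: np.ndarray
    SvO2: np.ndarray
    V_blood: np.ndarray
    HbO2_tis: np.ndarray
    HHb_tis: np.ndarray
    HbT_tis: np.ndarray
    oxCCO_tis: np.ndarray
    dHbO2: np.ndarray
    dHHb: np.ndarray
    dHbT: np.ndarray
    dOxCCO: np.ndarray
    rCBF: np.ndarray
    rCMRO2: np.ndarray
    rCBV: np.ndarray
    Pa: np.ndarray
    u: np.ndarray
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Δ-signal table in the canonical CSV column order."""
        return pd.DataFrame({c: getattr(self, {"Pa": "Pa"}.get(c, c)) for c in _CSV_COLUMNS})

    def write_csv(self, path: str | Path, sidecar: bool = True) -> Path:
        """Write the Δ-signal table as CSV plus a JSON metadata sidecar."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        if sidecar:
            side = path.with_suffix(path.suffix + ".json")
            side.write_text(json.dumps(self.metadata, indent=2, sort_keys=True))
        return path


def _derived_arrays(
    mu: np.ndarray,
    o2t: np.ndarray,
    a: np.ndarray,
    timeline: InputTimeline,
    params: ParameterSet,
) -> dict[str, np.ndarray]:
    """Vectorised counterpart of model_core.derived_quantities over a grid."""
    p_a = np.asarray(timeline.P_a, dtype=float)
    sao2 = np.asarray(timeline.SaO2, dtype=float)
    u = np.asarray(timeline.u, dtype=float)
    m = np.asarray(timeline.m, dtype=float)
    r = params.r_n * (1.0 - params.k_r * mu) * m
    cbf = params.K_flow * r ** 4 * (p_a - params.P_ic_n)
    if timeline.cbf_clamped:
        cbf = np.full_like(cbf, params.CBF_n)
    g_n = params.O2t_n / (params.O2t_n + params.K_mO2)
    lim = o2t / (o2t + params.K_mO2) / g_n
    cmro2 = params.CMRO2_n * (1.0 + params.k_m * (u - 1.0)) * lim
    svo2 = sao2 - cmro2 / (cbf * params.Hbtot)
    if np.any(svo2 < 0.0):
        i = int(np.argmax(svo2 < 0.0))
        raise SimulationError(
            f"at t={timeline.time[i]:.3f} s: venous saturation {svo2[i]:.4f} < 0 "
            "(oxygen supply exhausted)"
        )
    w_art = params.f_art * (r / params.r_n) ** 2
    v_blood = params.V_blood_n * (w_art + (1.0 - params.f_art))
    s_mean = (w_art * sao2 + (1.0 - params.f_art) * svo2) / (w_art + (1.0 - params.f_art))
    hbt = 1000.0 * params.Hbtot * v_blood
    hbo2 = hbt * s_mean
    return {
        "r": r, "CBF": cbf, "CMRO2": cmro2, "SvO2": svo2, "V_blood": v_blood,
        "HbO2_tis": hbo2, "HHb_tis": hbt - hbo2, "HbT_tis": hbt,
        "oxCCO_tis": a * params.CCO_tis,
    }


def _make_fast_rhs(timeline: InputTimeline, params: ParameterSet):
    """Scalar closure equivalent to model_core.model_rhs over the timeline.

    Inlines the closure equations with plain-float arithmetic for the
    integrator's inner loop; agreement with ``model_rhs`` is covered by a
    dedicated equivalence test.
    """
    import math

    p = params
    clamped = timeline.cbf_clamped
    at = timeline.at
    g_n = p.O2t_n / (p.O2t_n + p.K_mO2)
    eps = 0.01

    def rhs(ti: float, y) -> list[float]:
        p_a, sao2, paco2, u, m = at(ti)
        mu, o2t, a = float(y[0]), float(y[1]), float(y[2])
        o2t = o2t if o2t > 0.0 else 0.0
        r = p.r_n * (1.0 - p.k_r * mu) * m
        cbf = p.CBF_n if clamped else p.K_flow * r ** 4 * (p_a - p.P_ic_n)
        lim = o2t / (o2t + p.K_mO2) / g_n
        cmro2 = p.CMRO2_n * (1.0 + p.k_m * (u - 1.0)) * lim
        svo2 = sao2 - cmro2 / (cbf * p.Hbtot)
        if svo2 < 0.0:
            svo2 = eps * math.log1p(math.exp(svo2 / eps))
        eta = (
            p.R_P * (p_a / p.P_a_n - 1.0)
            + p.R_C * (1.0 - paco2 / p.PaCO2_n)
            + p.R_O * (o2t / p.O2t_n - 1.0)
            + p.R_u * (1.0 - u)
        )
        dmu = (math.tanh(eta) - mu) / p.tau_mu
        s_cap = 0.5 * (sao2 + svo2)
        do2t = p.kappa_O2 * (
            p.D_O2 * (s_cap * p.Hbtot - p.sigma_O2 * o2t) - cmro2
        )
        da = p.k_CuA * (lim * (1.0 - a) - p.k_red_ratio * u * a)
        return [dmu, do2t, da]

    return rhs


def _baseline_mean(time: np.ndarray, values: np.ndarray) -> float:
    mask = time <= time[0] + BASELINE_WINDOW
    return float(np.mean(values[mask]))


def _params_hash(params: ParameterSet) -> str:
    payload = json.dumps(params.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run(
    params: ParameterSet,
    timeline: InputTimeline,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    metadata: dict | None = None,
) -> Trajectory:
    """Integrate the model over a timeline and assemble the trajectory.

    The initial state is the steady state under the timeline's first-sample
    inputs, so a timeline that opens with a baseline hold starts (and stays)
    at equilibrium until the stimulus arrives.  Output is sampled on the
    timeline's own grid.
    """
    t = timeline.time
    first = InstantaneousInputs(
        *(float(np.asarray(ch)[0]) for ch in (timeline.P_a, timeline.SaO2, timeline.PaCO2, timeline.u, timeline.m)),
        cbf_clamped=timeline.cbf_clamped,
    )
    y0 = steady_state(params, first).as_array()

    rhs = _make_fast_rhs(timeline, params)

    sol = solve_ivp(
        rhs, (t[0], t[-1]), y0, method="LSODA", t_eval=t, rtol=rtol, atol=atol
    )
    if not sol.success:
        raise SimulationError(f"integrator failed: {sol.message}")

    mu = np.clip(sol.y[0], -1.0, 1.0)
    o2t = np.maximum(sol.y[1], 0.0)
    a = np.clip(sol.y[2], 0.0, 1.0)
    # clipping only removes round-off excursions; anything larger is an error
    slack = 1e-9
    if (
        np.any(np.abs(sol.y[0]) > 1.0 + slack)
        or np.any(sol.y[1] < -slack)
        or np.any((sol.y[2] < -slack) | (sol.y[2] > 1.0 + slack))
    ):
        raise SimulationError("integrated state left its physical bounds")

    cols = _derived_arrays(mu, o2t, a, timeline, params)

    d_hbo2 = cols["HbO2_tis"] - _baseline_mean(t, cols["HbO2_tis"])
    d_hhb = cols["HHb_tis"] - _baseline_mean(t, cols["HHb_tis"])
    d_oxcco = cols["oxCCO_tis"] - _baseline_mean(t, cols["oxCCO_tis"])
    meta = dict(metadata or {})
    meta.setdefault("params_hash", _params_hash(params))
    meta.setdefault("cbf_clamped", bool(timeline.cbf_clamped))
    return Trajectory(
        time=t.copy(),
        mu=mu, O2t=o2t, a=a,
        dHbO2=d_hbo2,
        dHHb=d_hhb,
        dHbT=d_hbo2 + d_hhb,  # additive by construction
        dOxCCO=d_oxcco,
        rCBF=cols["CBF"] / _baseline_mean(t, cols["CBF"]),
        rCMRO2=cols["CMRO2"] / _baseline_mean(t, cols["CMRO2"]),
        rCBV=cols["V_blood"] / _baseline_mean(t, cols["V_blood"]),
        Pa=np.asarray(timeline.P_a, dtype=float).copy(),
        u=np.asarray(timeline.u, dtype=float).copy(),
        metadata=meta,
        **cols,
    )


def block_average(trajectories: Sequence[Trajectory]) -> Trajectory:
    """Sample-wise mean of a set of trajectories on identical grids.

    Δ-signals are averaged and re-zeroed to the mean of the pre-stimulus
    baseline window, mirroring block-averaged stimulus-evoked recordings.
    """
    if len(trajectories) == 0:
        raise AlignmentError("need at least one trajectory")
    ref = trajectories[0]
    for traj in trajectories[1:]:
        if traj.time.shape != ref.time.shape or not np.array_equal(traj.time, ref.time):
            raise AlignmentError("trajectories are not on identical time grids")

    def mean_of(name: str) -> np.ndarray:
        return np.mean([getattr(tr, name) for tr in trajectories], axis=0)

    fields = {
        name: mean_of(name)
        for name in (
            "mu", "O2t", "a", "r", "CBF", "CMRO2", "SvO2", "V_blood",
            "HbO2_tis", "HHb_tis", "HbT_tis", "oxCCO_tis",
            "rCBF", "rCMRO2", "rCBV", "Pa", "u",
        )
    }
    t = ref.time
    d_hbo2 = mean_of("dHbO2")
    d_hhb = mean_of("dHHb")
    d_oxcco = mean_of("dOxCCO")
    d_hbo2 = d_hbo2 - _baseline_mean(t, d_hbo2)
    d_hhb = d_hhb - _baseline_mean(t, d_hhb)
    d_oxcco = d_oxcco - _baseline_mean(t, d_oxcco)
    return Trajectory(
        time=t.copy(),
        dHbO2=d_hbo2,
        dHHb=d_hhb,
        dHbT=d_hbo2 + d_hhb,
        dOxCCO=d_oxcco,
        metadata={"block_average_of": len(trajectories)},
        **fields,
    )
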