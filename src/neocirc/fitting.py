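"""Least-squares estimation of stimulus amplitudes from measured Δ-signals.

A scenario serves as the forward template; the free subset of
(alpha, beta, gamma) is estimated by bounded multi-start local least squares
against whichever Δ-channels the traces supply, all channels equally
weighted in μM.  A numerical-Jacobian condition number flags flat
(non-identifiable) directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import AmplitudeError, SimulationError, SteadyStateError, TraceDataError
from .model_core import ParameterSet, load_preset
from .scenarios import Scenario
from .simulate import run
from .stimulus import build_timeline

__all__ = ["MeasuredTraces", "FitResult", "fit_amplitudes", "AMPLITUDE_BOUNDS"]

#: search bounds per amplitude
AMPLITUDE_BOUNDS = {"alpha": (0.0, 5.0), "beta": (-10.0, 10.0), "gamma": (0.0, 0.05)}

#: Jacobian condition number above which the fit is flagged non-identifiable
FLAT_DIRECTION_CONDITION = 1e4

_CHANNELS = ("dHbO2", "dHHb", "dHbT")


@dataclass
class MeasuredTraces:
    """Measured (or synthetic) Δ-signal traces in μM on a common time base.

    Any subset of the three channels may be present; a missing ΔHbT is
    reconstructed as ΔHbO2 + ΔHHb when both components exist.
    """

    time: np.ndarray
    dHbO2: np.ndarray | None = None
    dHHb: np.ndarray | None = None
    dHbT: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        if t.ndim != 1 or len(t) < 10:
            raise TraceDataError("traces need at least 10 samples")
        if np.any(np.diff(t) <= 0):
            raise TraceDataError("trace time base must be strictly increasing")
        self.time = t
        present = 0
        for name in _CHANNELS:
            arr = getattr(self, name)
            if arr is None:
                continue
            arr = np.asarray(arr, dtype=float)
            if arr.shape != t.shape:
                raise TraceDataError(f"channel {name!r} shape mismatch")
            setattr(self, name, arr)
            present += 1
        if present == 0:
            raise TraceDataError("traces contain no Δ-signal channel")
        if self.dHbT is None and self.dHbO2 is not None and self.dHHb is not None:
            self.dHbT = self.dHbO2 + self.dHHb

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(name for name in _CHANNELS if getattr(self, name) is not None)

    def validate_finite(self) -> None:
        for name in self.channels:
            if not np.all(np.isfinite(getattr(self, name))):
                raise TraceDataError(f"channel {name!r} contains non-finite values")
        if not np.all(np.isfinite(self.time)):
            raise TraceDataError("time base contains non-finite values")

    @classmethod
    def from_csv(cls, path: str | Path) -> "MeasuredTraces":
        df = pd.read_csv(path)
        if "time" not in df.columns:
            raise TraceDataError(f"{path}: missing 'time' column")
        kwargs = {
            name: df[name].to_numpy() for name in _CHANNELS if name in df.columns
        }
        return cls(time=df["time"].to_numpy(), **kwargs)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        data = {"time": self.time}
        data.update({name: getattr(self, name) for name in self.channels})
        pd.DataFrame(data).to_csv(path, index=False)
        return path


@dataclass
class FitResult:
    """Outcome of one amplitude fit."""

    amplitudes: dict[str, float]
    free: tuple[str, ...]
    rss: float
    rmse_per_channel: dict[str, float]
    converged: bool
    n_forward_evals: int
    jacobian_condition: float | None = None
    flat_direction: bool = False
    starts: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "amplitudes": self.amplitudes,
            "free": list(self.free),
            "rss": self.rss,
            "rmse_per_channel": self.rmse_per_channel,
            "converged": self.converged,
            "n_forward_evals": self.n_forward_evals,
            "jacobian_condition": self.jacobian_condition,
            "flat_direction": self.flat_direction,
        }


def _forward_deltas(
    template: Scenario,
    params: ParameterSet,
    amplitudes: dict[str, float],
    trace_time: np.ndarray,
    channels: tuple[str, ...],
    rtol: float,
    atol: float,
) -> dict[str, np.ndarray]:
    sc = template.with_amplitudes(**amplitudes)
    grid = sc.time_grid()
    timeline = build_timeline(sc.amplitudes, sc.hrf, params, grid, clamp_cbf=sc.clamp_cbf)
    traj = run(params, timeline, rtol=rtol, atol=atol)
    return {
        name: np.interp(trace_time, traj.time, getattr(traj, name))
        for name in channels
    }


def fit_amplitudes(
    traces: MeasuredTraces,
    template: Scenario,
    free: tuple[str, ...] | list[str] = ("alpha",),
    *,
    seed: int = 0,
    n_starts: int = 3,
    params: ParameterSet | None = None,
    rtol: float = 1e-7,
    atol: float = 1e-9,
    weights: dict[str, float] | None = None,
) -> FitResult:
    """Estimate the free stimulus amplitudes by bounded least squares.

    The first start is the template's own amplitudes; the remaining
    ``n_starts − 1`` starts are drawn uniformly inside the bounds from a
    seeded generator, and the lowest-cost solution is retained.  With
    ``free`` empty the residual is evaluated at the template amplitudes
    without optimisation.
    """
    free = tuple(free)
    for name in free:
        if name not in AMPLITUDE_BOUNDS:
            raise ValueError(f"unknown amplitude {name!r}")
    traces.validate_finite()
    if params is None:
        params = load_preset(template.preset)
    channels = traces.channels
    w = {name: 1.0 for name in channels}
    if weights:
        w.update({k: float(v) for k, v in weights.items() if k in w})
    measured = np.concatenate(
        [np.sqrt(w[name]) * getattr(traces, name) for name in channels]
    )

    base_amps = {
        "alpha": template.amplitudes.alpha,
        "beta": template.amplitudes.beta,
        "gamma": template.amplitudes.gamma,
    }
    n_evals = 0

    def residuals(theta: np.ndarray) -> np.ndarray:
        nonlocal n_evals
        n_evals += 1
        amps = dict(base_amps)
        amps.update({name: float(v) for name, v in zip(free, theta)})
        try:
            model = _forward_deltas(
                template, params, amps, traces.time, channels, rtol, atol
            )
        except (AmplitudeError, SimulationError, SteadyStateError):
            # infeasible amplitudes inside the box bounds: finite penalty
            # so the search backs away instead of aborting
            return np.full(measured.shape, 1e3 * (1.0 + float(np.abs(theta).sum())))
        return (
            np.concatenate([np.sqrt(w[name]) * model[name] for name in channels])
            - measured
        )

    if not free:
        res = residuals(np.empty(0))
        rss = float(res @ res)
        return FitResult(
            amplitudes=base_amps,
            free=free,
            rss=rss,
            rmse_per_channel=_rmse_split(res, channels),
            converged=True,
            n_forward_evals=n_evals,
        )

    lb = np.array([AMPLITUDE_BOUNDS[name][0] for name in free])
    ub = np.array([AMPLITUDE_BOUNDS[name][1] for name in free])
    rng = np.random.default_rng(seed)
    x0s = [np.clip([base_amps[name] for name in free], lb, ub)]
    for _ in range(n_starts - 1):
        x0s.append(lb + rng.uniform(size=len(free)) * (ub - lb))

    best = None
    starts_log = []
    for x0 in x0s:
        sol = least_squares(
            residuals, x0, bounds=(lb, ub), method="trf",
            # diff_step large enough that finite differences of the forward
            # model clear its ODE-integration noise floor
            xtol=1e-10, ftol=1e-10, gtol=1e-10, diff_step=1e-2,
        )
        starts_log.append(
            {"x0": list(map(float, x0)), "x": list(map(float, sol.x)),
             "cost": float(sol.cost), "success": bool(sol.success)}
        )
        if best is None or sol.cost < best.cost:
            best = sol

    est = dict(base_amps)
    est.update({name: float(v) for name, v in zip(free, best.x)})
    res = best.fun
    cond = _diagnostic_condition(
        template, params, base_amps, free, best.x, traces.time, channels, w
    )
    return FitResult(
        amplitudes=est,
        free=free,
        rss=float(res @ res),
        rmse_per_channel=_rmse_split(res, channels),
        converged=any(s["success"] for s in starts_log),
        n_forward_evals=n_evals,
        jacobian_condition=cond,
        flat_direction=bool(cond > FLAT_DIRECTION_CONDITION),
        starts=starts_log,
    )


def _diagnostic_condition(
    template: Scenario,
    params: ParameterSet,
    base_amps: dict[str, float],
    free: tuple[str, ...],
    x: np.ndarray,
    trace_time: np.ndarray,
    channels: tuple[str, ...],
    weights: dict[str, float],
    *,
    step: float = 0.01,
) -> float:
    """Condition number of a central-difference Jacobian at the solution.

    Central differences at tight integrator tolerance keep the truncation
    error O(step²), so an exactly flat direction is not masked by
    finite-difference noise the way it is in the optimiser's own forward-
    difference Jacobian.
    """

    def model_vec(theta: np.ndarray) -> np.ndarray:
        amps = dict(base_amps)
        amps.update({name: float(v) for name, v in zip(free, theta)})
        model = _forward_deltas(
            template, params, amps, trace_time, channels, 1e-10, 1e-12
        )
        return np.concatenate(
            [np.sqrt(weights[name]) * model[name] for name in channels]
        )

    cols = []
    for j in range(len(free)):
        h = step * max(1.0, abs(float(x[j])))
        e = np.zeros_like(x, dtype=float)
        e[j] = h
        try:
            cols.append((model_vec(x + e) - model_vec(x - e)) / (2.0 * h))
        except (AmplitudeError, SimulationError, SteadyStateError):
            # one-sided fallback at a feasibility boundary
            cols.append((model_vec(x) - model_vec(x - e)) / h)
    jac = np.column_stack(cols)
    sv = np.linalg.svd(jac, compute_uv=False)
    return float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf


def _rmse_split(residual: np.ndarray, channels: tuple[str, ...]) -> dict[str, float]:
    per = np.split(residual, len(channels))
    return {
        name: float(np.sqrt(np.mean(chunk ** 2)))
        for name, chunk in zip(channels, per)
    }
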