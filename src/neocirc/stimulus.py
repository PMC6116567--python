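"""Haemodynamic response function and stimulus timeline construction.

The temporal kernel is the canonical difference of two gamma densities
(positive lobe peaking early, delayed undershoot lobe).  A sustained
stimulus is modelled by convolving the kernel with a boxcar of the stimulus
duration; the result is re-normalised to unit peak so that every amplitude
parameter denotes the *peak* excursion of its channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import AmplitudeError, DomainBoundError, GridResolutionError
from .model_core import ParameterSet

__all__ = ["HRFSpec", "StimulusAmplitudes", "InputTimeline", "make_hrf", "build_timeline"]


@dataclass(frozen=True)
class HRFSpec:
    """Shape and timing of the haemodynamic response function."""

    peak_time: float = 5.0          # s, mode of the positive lobe
    undershoot_time: float = 15.0   # s, mode of the undershoot lobe
    undershoot_ratio: float = 0.35  # undershoot amplitude relative to peak lobe
    stimulus_onset: float = 10.0    # s
    stimulus_duration: float = 10.0  # s

    def __post_init__(self) -> None:
        if not self.peak_time > 0 or not self.stimulus_duration > 0:
            raise DomainBoundError("HRF peak_time and stimulus_duration must be > 0")
        if not self.peak_time < self.undershoot_time:
            raise DomainBoundError("HRF peak_time must precede undershoot_time")
        if self.undershoot_ratio < 0:
            raise DomainBoundError("HRF undershoot_ratio must be >= 0")
        if self.stimulus_onset < 0:
            raise DomainBoundError("HRF stimulus_onset must be >= 0")


@dataclass(frozen=True)
class StimulusAmplitudes:
    """Peak excursions of the three stimulus channels.

    ``alpha`` scales demand (u = 1 + alpha·HRF), ``beta`` scales pressure
    with the sign convention P_a = P_a_n − beta·HRF (positive beta is a
    pressure *decrease*; a pressure rise uses negative beta), and ``gamma``
    scales a direct radius reduction (m = 1 − gamma·HRF).
    """

    alpha: float = 0.0  # demand amplitude, dimensionless
    beta: float = 0.0   # pressure-decrease amplitude, mmHg
    gamma: float = 0.0  # radius-reduction amplitude, dimensionless

    def replace(self, **changes) -> "StimulusAmplitudes":
        import dataclasses

        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class InputTimeline:
    """Externally imposed input channels sampled on a common time grid."""

    time: np.ndarray    # s, strictly increasing
    P_a: np.ndarray     # mmHg
    SaO2: np.ndarray    # fraction
    PaCO2: np.ndarray   # mmHg
    u: np.ndarray       # demand
    m: np.ndarray       # radius modulation
    cbf_clamped: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        if t.ndim != 1 or len(t) < 2 or np.any(np.diff(t) <= 0):
            raise DomainBoundError("timeline time grid must be strictly increasing")
        for name in ("P_a", "SaO2", "PaCO2", "u", "m"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != t.shape:
                raise DomainBoundError(f"timeline channel {name!r} shape mismatch")

    def _stacked(self) -> tuple[np.ndarray, float | None]:
        """Channel matrix and, for uniform grids, the time step (cached)."""
        cache = self.__dict__.get("_cache")
        if cache is None:
            t = np.asarray(self.time, dtype=float)
            mat = np.vstack(
                [np.asarray(getattr(self, n), dtype=float) for n in ("P_a", "SaO2", "PaCO2", "u", "m")]
            )
            steps = np.diff(t)
            dt = float(steps[0]) if np.allclose(steps, steps[0], rtol=1e-9, atol=0) else None
            cache = (mat, dt)
            # frozen dataclass: bypass __setattr__ for the lazy cache
            object.__setattr__(self, "_cache", cache)
        return cache

    def at(self, t: float) -> tuple[float, float, float, float, float]:
        """Linearly interpolated inputs (P_a, SaO2, PaCO2, u, m) at time t."""
        mat, dt = self._stacked()
        time = self.time
        n = len(time)
        if dt is not None:
            x = (t - time[0]) / dt
            i = int(x)
            if x <= 0:
                return tuple(mat[:, 0])
            if i >= n - 1:
                return tuple(mat[:, n - 1])
            frac = x - i
        else:
            i = int(np.searchsorted(time, t, side="right")) - 1
            if i < 0:
                return tuple(mat[:, 0])
            if i >= n - 1:
                return tuple(mat[:, n - 1])
            frac = (t - time[i]) / (time[i + 1] - time[i])
        lo = mat[:, i]
        return tuple(lo + frac * (mat[:, i + 1] - lo))


def _lobe_cdf(x: np.ndarray, mode: float) -> np.ndarray:
    """CDF of a unit-scale gamma density whose mode sits at ``mode``."""
    return stats.gamma.cdf(x, a=mode + 1.0, scale=1.0)


def make_hrf(spec: HRFSpec, time_grid: np.ndarray) -> np.ndarray:
    """Evaluate the peak-normalised HRF on a time grid.

    The kernel (difference of two gamma densities with modes at
    ``peak_time`` and ``undershoot_time``) is convolved with the stimulus
    boxcar analytically — the convolution of a density with a boxcar is a
    difference of its CDFs — and then scaled so the maximum over the grid
    is exactly 1.  The response is identically zero before stimulus onset.
    """
    t = np.asarray(time_grid, dtype=float)
    if t.ndim != 1 or len(t) < 2 or np.any(np.diff(t) <= 0):
        raise DomainBoundError("time grid must be 1-D and strictly increasing")
    max_step = float(np.max(np.diff(t)))
    if max_step > spec.peak_time / 4.0:
        raise GridResolutionError(
            f"grid spacing {max_step:.3g} s too coarse to resolve the "
            f"{spec.peak_time:.3g} s response peak (need <= peak_time/4)"
        )

    def kernel_integral(x: np.ndarray) -> np.ndarray:
        return _lobe_cdf(x, spec.peak_time) - spec.undershoot_ratio * _lobe_cdf(
            x, spec.undershoot_time
        )

    since_on = t - spec.stimulus_onset
    since_off = since_on - spec.stimulus_duration
    raw = kernel_integral(since_on) - kernel_integral(since_off)
    raw[since_on <= 0] = 0.0
    peak = float(np.max(raw))
    if peak <= 0:
        raise GridResolutionError("grid does not cover the response peak")
    return raw / peak


def build_timeline(
    amps: StimulusAmplitudes,
    spec: HRFSpec,
    params: ParameterSet,
    time_grid: np.ndarray,
    clamp_cbf: bool = False,
) -> InputTimeline:
    """Assemble the model input channels for one stimulus experiment.

    Demand, pressure and radius modulation follow the HRF with their
    respective amplitudes; arterial saturation and CO2 are held constant at
    their normal values.
    """
    hrf = make_hrf(spec, time_grid)
    t = np.asarray(time_grid, dtype=float)
    u = 1.0 + amps.alpha * hrf
    m = 1.0 - amps.gamma * hrf
    if np.min(u) <= 0:
        raise AmplitudeError(f"alpha={amps.alpha} drives demand u <= 0")
    if np.min(m) <= 0:
        raise AmplitudeError(f"gamma={amps.gamma} drives radius modulation m <= 0")
    p_a = params.P_a_n - amps.beta * hrf
    if np.min(p_a) <= params.P_ic_n:
        raise AmplitudeError(
            f"beta={amps.beta} drives arterial pressure below intracranial pressure"
        )
    return InputTimeline(
        time=t,
        P_a=p_a,
        SaO2=np.full_like(t, params.SaO2_n),
        PaCO2=np.full_like(t, params.PaCO2_n),
        u=u,
        m=m,
        cbf_clamped=clamp_cbf,
    )
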