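"""Reduced lumped-parameter model of cerebral haemodynamics and O2 metabolism.

The model tracks three dynamic states — vascular smooth-muscle tone ``mu``,
tissue oxygen concentration ``O2t`` and the oxidised CuA fraction ``a`` — and
derives flow, metabolism, blood volume and tissue haemoglobin/oxCCO
observables algebraically.  All closure constants (``K_flow``, ``D_O2``,
``sigma_O2``, ``kappa_O2``, ``k_red_ratio``) are solved once by
:func:`calibrate` so that the published normal values form an exact fixed
point of the dynamics.

Units: pressures mmHg, blood flow ml·100g⁻¹·min⁻¹, metabolic rate
μmol·100g⁻¹·min⁻¹, blood haemoglobin mM (haem units: one O2 binding site per
haem, so flow × concentration × saturation is directly an O2 delivery rate in
μmol·100g⁻¹·min⁻¹), tissue concentrations μM, time seconds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources
from typing import Iterable

import numpy as np
import yaml
from scipy import optimize

from .errors import (
    CalibrationError,
    ConfigurationError,
    DomainBoundError,
    OxygenSupplyExhaustedError,
    SteadyStateError,
)

__all__ = [
    "ParameterSet",
    "ModelState",
    "InstantaneousInputs",
    "DerivedQuantities",
    "calibrate",
    "baseline_state",
    "baseline_inputs",
    "model_rhs",
    "derived_quantities",
    "steady_state",
    "subject_overrides",
    "haemoglobin_to_haem_mM",
    "load_preset",
    "PRESET_NAMES",
]

#: grams of haemoglobin tetramer per mole
_HB_MOLAR_MASS_G = 64500.0
#: haem groups (O2 binding sites) per tetramer
_HAEM_PER_TETRAMER = 4.0

# Fields that must be strictly positive.
_POSITIVE_FIELDS = (
    "CBF_n", "CCO_tis", "CMRO2_n", "P_a_n", "Hbtot", "V_blood_n", "P_ic_n",
    "PaCO2_n", "r_n", "tau_mu", "K_mO2", "O2t_n", "k_CuA", "tau_O2",
)
# Fields that must lie strictly inside (0, 1).
_UNIT_INTERVAL_FIELDS = ("CuA_frac_n", "V_blood_n", "f_art", "k_r", "sigma_frac")

_CLOSURE_FIELDS = ("K_flow", "D_O2", "sigma_O2", "kappa_O2", "k_red_ratio")


@dataclass(frozen=True)
class ParameterSet:
    """Physiological constants for one subject or population.

    The first eight fields mirror the published normal values for the adult
    and preterm populations; the remainder are closure constants of this
    reduced model with documented defaults.  Closure constants solved by
    :func:`calibrate` start as ``None``.
    """

    CBF_n: float            # normal cerebral blood flow, ml/100g/min
    CCO_tis: float          # total tissue cytochrome-c-oxidase, μM
    CuA_frac_n: float       # normal oxidised CuA fraction
    CMRO2_n: float          # normal O2 consumption rate, μmol/100g/min
    P_a_n: float            # normal mean arterial pressure, mmHg
    Hbtot: float            # blood haemoglobin, mM haem units
    V_blood_n: float        # normal blood volume fraction
    P_ic_n: float           # intracranial pressure, mmHg

    SaO2_n: float = 0.96    # normal arterial O2 saturation
    PaCO2_n: float = 40.0   # normal arterial CO2 tension, mmHg
    f_art: float = 0.25     # arterial fraction of blood volume
    r_n: float = 1.0        # normal arterial radius (arbitrary units)

    tau_mu: float = 5.0     # vascular tone time constant, s
    R_P: float = 3.0        # autoregulatory pressure gain
    R_O: float = 1.0        # autoregulatory tissue-O2 gain
    R_C: float = 1.0        # autoregulatory CO2 gain
    R_u: float = 1.5        # demand→tone gain (dilation)
    k_r: float = 0.12       # maximal fractional radius excursion
    k_m: float = 0.15       # demand→CMRO2 coupling gain
    K_mO2: float = 0.005    # Michaelis constant for O2 limitation, mM
    O2t_n: float = 0.024    # normal tissue O2 concentration, mM
    k_CuA: float = 0.5      # CuA redox relaxation rate, 1/s
    tau_O2: float = 2.0     # tissue O2 pool time constant, s
    sigma_frac: float = 0.5  # back-pressure fraction of capillary O2 content

    # closure constants, set by calibrate()
    K_flow: float | None = None
    D_O2: float | None = None
    sigma_O2: float | None = None
    kappa_O2: float | None = None
    k_red_ratio: float | None = None

    def __post_init__(self) -> None:
        for name in _POSITIVE_FIELDS:
            if not getattr(self, name) > 0:
                raise DomainBoundError(f"parameter {name!r} must be > 0")
        for name in _UNIT_INTERVAL_FIELDS:
            if not 0 < getattr(self, name) < 1:
                raise DomainBoundError(f"parameter {name!r} must lie in (0, 1)")
        if not 0 < self.SaO2_n <= 1:
            raise DomainBoundError("parameter 'SaO2_n' must lie in (0, 1]")
        if self.P_a_n <= self.P_ic_n:
            raise DomainBoundError(
                "normal arterial pressure must exceed intracranial pressure"
            )

    @property
    def is_calibrated(self) -> bool:
        # calibrate() sets all closure fields together, so one check suffices
        return self.k_red_ratio is not None

    @property
    def SvO2_n(self) -> float:
        """Baseline venous O2 saturation implied by the Fick principle."""
        return self.SaO2_n - self.CMRO2_n / (self.CBF_n * self.Hbtot)

    @property
    def OEF_n(self) -> float:
        """Baseline oxygen extraction fraction."""
        return self.CMRO2_n / (self.CBF_n * self.Hbtot * self.SaO2_n)

    def replace(self, **changes) -> "ParameterSet":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class ModelState:
    """Dynamic state of the reduced model."""

    mu: float   # vascular smooth-muscle tone, in [-1, 1]
    O2t: float  # tissue O2 concentration, mM, >= 0
    a: float    # oxidised CuA fraction, in [0, 1]

    def validate(self) -> None:
        if not -1.0 <= self.mu <= 1.0:
            raise DomainBoundError(f"tone mu={self.mu} outside [-1, 1]")
        if not self.O2t >= 0.0:
            raise DomainBoundError(f"tissue O2 O2t={self.O2t} below 0")
        if not 0.0 <= self.a <= 1.0:
            raise DomainBoundError(f"oxidised CuA fraction a={self.a} outside [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.mu, self.O2t, self.a], dtype=float)

    @classmethod
    def from_array(cls, y: Iterable[float]) -> "ModelState":
        return cls(mu=float(y[0]), O2t=float(y[1]), a=float(y[2]))


@dataclass(frozen=True)
class InstantaneousInputs:
    """Externally imposed inputs at one instant."""

    P_a: float              # arterial pressure, mmHg
    SaO2: float             # arterial O2 saturation
    PaCO2: float            # arterial CO2 tension, mmHg
    u: float = 1.0          # dimensionless demand
    m: float = 1.0          # multiplicative radius modulation
    cbf_clamped: bool = False

    def validate(self) -> None:
        if not self.u > 0:
            raise DomainBoundError(f"demand u={self.u} must be > 0")
        if not 0.0 <= self.SaO2 <= 1.0:
            raise DomainBoundError(f"SaO2={self.SaO2} outside [0, 1]")
        if not self.m > 0:
            raise DomainBoundError(f"radius modulation m={self.m} must be > 0")


@dataclass(frozen=True)
class DerivedQuantities:
    """Algebraic observables derived from one (state, inputs) pair."""

    r: float          # arterial radius, units of r_n
    CBF: float        # ml/100g/min
    CMRO2: float      # μmol/100g/min
    SvO2: float       # venous O2 saturation
    V_blood: float    # blood volume fraction
    HbO2_tis: float   # tissue oxyhaemoglobin, μM
    HHb_tis: float    # tissue deoxyhaemoglobin, μM
    HbT_tis: float    # tissue total haemoglobin, μM
    oxCCO_tis: float  # oxidised CCO, μM


def haemoglobin_to_haem_mM(haemoglobin_g_dL: float) -> float:
    """Convert a blood haemoglobin mass concentration (g/dL) to mM haem."""
    if not haemoglobin_g_dL > 0:
        raise DomainBoundError("haemoglobin must be > 0 g/dL")
    grams_per_litre = haemoglobin_g_dL * 10.0
    return grams_per_litre / _HB_MOLAR_MASS_G * _HAEM_PER_TETRAMER * 1000.0


def calibrate(params: ParameterSet) -> ParameterSet:
    """Solve the closure constants so the normal values are a fixed point.

    Sets ``K_flow`` (flow conductance), ``D_O2``/``sigma_O2``/``kappa_O2``
    (tissue O2 exchange) and ``k_red_ratio`` (CuA reduction/oxidation balance)
    such that the state (mu=0, O2t=O2t_n, a=CuA_frac_n) under baseline inputs
    is an exact equilibrium with CBF = CBF_n and CMRO2 = CMRO2_n.

    Raises
    ------
    CalibrationError
        If the parameters are infeasible (oxygen extraction fraction >= 1).
    """
    svo2_n = params.SvO2_n
    if not 0.0 < svo2_n < params.SaO2_n:
        raise CalibrationError(
            "infeasible parameters: baseline oxygen extraction fraction "
            f"{params.OEF_n:.3f} implies venous saturation {svo2_n:.3f}; "
            "need CMRO2_n < CBF_n * Hbtot * SaO2_n"
        )
    k_flow = params.CBF_n / (params.r_n ** 4 * (params.P_a_n - params.P_ic_n))
    # Capillary O2 content at baseline (mM haem-bound O2).
    s_cap_n = 0.5 * (params.SaO2_n + svo2_n)
    cap_o2_n = s_cap_n * params.Hbtot
    # Split the baseline diffusion driving force: sigma_frac of capillary
    # content is balanced by tissue back-pressure, the rest carries CMRO2_n.
    sigma = params.sigma_frac * cap_o2_n / params.O2t_n
    d_o2 = params.CMRO2_n / ((1.0 - params.sigma_frac) * cap_o2_n)
    # kappa converts the flux imbalance to mM/s and fixes the relaxation
    # time of the tissue O2 pool at tau_O2.
    kappa = 1.0 / (params.tau_O2 * d_o2 * sigma)
    k_red = (1.0 - params.CuA_frac_n) / params.CuA_frac_n
    return params.replace(
        K_flow=k_flow, D_O2=d_o2, sigma_O2=sigma, kappa_O2=kappa, k_red_ratio=k_red
    )


def baseline_state(params: ParameterSet) -> ModelState:
    """The calibrated equilibrium state."""
    return ModelState(mu=0.0, O2t=params.O2t_n, a=params.CuA_frac_n)


def baseline_inputs(params: ParameterSet, cbf_clamped: bool = False) -> InstantaneousInputs:
    """Baseline (resting) input values."""
    return InstantaneousInputs(
        P_a=params.P_a_n,
        SaO2=params.SaO2_n,
        PaCO2=params.PaCO2_n,
        u=1.0,
        m=1.0,
        cbf_clamped=cbf_clamped,
    )


def _require_calibrated(params: ParameterSet) -> None:
    if not params.is_calibrated:
        raise ConfigurationError(
            "parameter set is not calibrated; apply neocirc.model_core.calibrate first"
        )


def _o2_limitation(o2t: float, params: ParameterSet) -> float:
    """Michaelis factor g(O2t)/g(O2t_n) limiting O2-consuming rates."""
    g = o2t / (o2t + params.K_mO2)
    g_n = params.O2t_n / (params.O2t_n + params.K_mO2)
    return g / g_n


def _cmro2(o2t: float, u: float, params: ParameterSet) -> float:
    return params.CMRO2_n * (1.0 + params.k_m * (u - 1.0)) * _o2_limitation(o2t, params)


def derived_quantities(
    state: ModelState,
    inputs: InstantaneousInputs,
    params: ParameterSet,
    *,
    strict: bool = True,
) -> DerivedQuantities:
    """Evaluate the algebraic observables for one (state, inputs) pair.

    With ``strict=True`` (default) a venous saturation below zero raises
    :class:`OxygenSupplyExhaustedError`; solvers may pass ``strict=False`` to
    obtain a smooth continuation instead (never used for reported output).
    """
    _require_calibrated(params)
    r = params.r_n * (1.0 - params.k_r * state.mu) * inputs.m
    cbf_hydraulic = params.K_flow * r ** 4 * (inputs.P_a - params.P_ic_n)
    cbf = params.CBF_n if inputs.cbf_clamped else cbf_hydraulic
    cmro2 = _cmro2(state.O2t, inputs.u, params)
    svo2 = inputs.SaO2 - cmro2 / (cbf * params.Hbtot)
    if svo2 < 0.0:
        if strict:
            raise OxygenSupplyExhaustedError(
                f"venous saturation {svo2:.4f} < 0: oxygen demand "
                f"(CMRO2={cmro2:.2f}) exceeds supply (CBF={cbf:.2f}, "
                f"SaO2={inputs.SaO2:.3f})"
            )
        # smooth softplus floor, used only inside root finders
        eps = 0.01
        svo2 = eps * np.log1p(np.exp(svo2 / eps))
    w_art = params.f_art * (r / params.r_n) ** 2
    v_blood = params.V_blood_n * (w_art + (1.0 - params.f_art))
    # volume-weighted mean saturation over arterial + venous compartments
    s_mean = (w_art * inputs.SaO2 + (1.0 - params.f_art) * svo2) / (
        w_art + (1.0 - params.f_art)
    )
    hbt = 1000.0 * params.Hbtot * v_blood
    hbo2 = hbt * s_mean
    hhb = hbt - hbo2
    return DerivedQuantities(
        r=r,
        CBF=cbf,
        CMRO2=cmro2,
        SvO2=svo2,
        V_blood=v_blood,
        HbO2_tis=hbo2,
        HHb_tis=hhb,
        HbT_tis=hbt,
        oxCCO_tis=state.a * params.CCO_tis,
    )


def model_rhs(
    state: ModelState,
    inputs: InstantaneousInputs,
    params: ParameterSet,
    *,
    strict: bool = True,
) -> tuple[float, float, float]:
    """Time derivatives (dmu/dt, dO2t/dt, da/dt) in 1/s, mM/s, 1/s."""
    _require_calibrated(params)
    if strict:
        state.validate()
        inputs.validate()
    dq = derived_quantities(state, inputs, params, strict=strict)
    # vascular tone: pressure constricts; CO2, low O2 and demand dilate
    eta = (
        params.R_P * (inputs.P_a / params.P_a_n - 1.0)
        + params.R_C * (1.0 - inputs.PaCO2 / params.PaCO2_n)
        + params.R_O * (state.O2t / params.O2t_n - 1.0)
        + params.R_u * (1.0 - inputs.u)
    )
    dmu = (np.tanh(eta) - state.mu) / params.tau_mu
    # tissue O2 pool: capillary diffusion in, consumption out
    s_cap = 0.5 * (inputs.SaO2 + dq.SvO2)
    flux_in = params.D_O2 * (s_cap * params.Hbtot - params.sigma_O2 * state.O2t)
    do2t = params.kappa_O2 * (flux_in - dq.CMRO2)
    # CuA redox: O2-dependent oxidation vs demand-driven reduction
    lim = _o2_limitation(state.O2t, params)
    da = params.k_CuA * (
        lim * (1.0 - state.a) - params.k_red_ratio * inputs.u * state.a
    )
    return (float(dmu), float(do2t), float(da))


def steady_state(
    params: ParameterSet,
    inputs: InstantaneousInputs,
    *,
    tol: float = 1e-12,
    residual_tol: float = 1e-8,
) -> ModelState:
    """Solve for the equilibrium state under constant inputs.

    Deterministic: always starts from the calibrated baseline state.  The
    returned state has every time derivative below ``residual_tol`` in
    magnitude.
    """
    _require_calibrated(params)
    inputs.validate()

    def residual(y: np.ndarray) -> np.ndarray:
        st = ModelState.from_array(np.clip(y, [-1.0, 0.0, 0.0], [1.0, np.inf, 1.0]))
        return np.array(model_rhs(st, inputs, params, strict=False))

    y0 = baseline_state(params).as_array()
    sol = optimize.root(residual, y0, method="hybr", tol=tol)
    y = np.clip(sol.x, [-1.0, 0.0, 0.0], [1.0, np.inf, 1.0])
    state = ModelState.from_array(y)
    try:
        res = np.array(model_rhs(state, inputs, params, strict=True))
    except OxygenSupplyExhaustedError as exc:
        raise SteadyStateError(
            f"no physical steady state for inputs {inputs}: {exc}"
        ) from exc
    res_norm = float(np.max(np.abs(res)))
    if res_norm > residual_tol:
        raise SteadyStateError(
            f"steady-state solver did not converge: residual norm {res_norm:.3e} "
            f"> {residual_tol:.1e} for inputs {inputs}"
        )
    return state


def subject_overrides(
    base: ParameterSet,
    haemoglobin_g_dL: float | None = None,
    baseline_SpO2: float | None = None,
) -> ParameterSet:
    """Apply subject-specific haemoglobin / baseline saturation overrides.

    Haemoglobin is converted from the clinically reported g/dL to mM haem
    units; the result is re-calibrated.  With no overrides the base set is
    returned unchanged.
    """
    if haemoglobin_g_dL is None and baseline_SpO2 is None:
        return base
    changes: dict[str, float] = {}
    if haemoglobin_g_dL is not None:
        changes["Hbtot"] = haemoglobin_to_haem_mM(haemoglobin_g_dL)
    if baseline_SpO2 is not None:
        if not 0.0 < baseline_SpO2 <= 1.0:
            raise DomainBoundError("baseline_SpO2 must lie in (0, 1]")
        changes["SaO2_n"] = baseline_SpO2
    return calibrate(base.replace(**changes))


# ---------------------------------------------------------------------------
# presets

PRESET_NAMES = ("adult", "preterm", "neonate1", "neonate2")

# Published normal values the population presets must reproduce.
_PRESET_CHECKS = {
    "adult": dict(
        CBF_n=49.0, CCO_tis=5.5, CuA_frac_n=0.8, CMRO2_n=155.0,
        P_a_n=100.0, Hbtot=9.1, V_blood_n=0.04, P_ic_n=9.5,
    ),
    "preterm": dict(
        CBF_n=19.8, CCO_tis=2.2, CuA_frac_n=0.67, CMRO2_n=40.865,
        P_a_n=30.0, Hbtot=9.75, V_blood_n=0.0233, P_ic_n=5.1,
    ),
}


def load_preset(name: str, calibrated: bool = True) -> ParameterSet:
    """Load a shipped parameter preset by name.

    The ``adult`` and ``preterm`` population presets are validated against
    their published normal values at load time.
    """
    if name not in PRESET_NAMES:
        raise KeyError(f"unknown preset {name!r}; available: {PRESET_NAMES}")
    text = resources.files("neocirc.presets").joinpath(f"{name}.yaml").read_text()
    fields = yaml.safe_load(text)
    params = ParameterSet(**fields)
    expected = _PRESET_CHECKS.get(name)
    if expected is not None:
        for key, value in expected.items():
            if getattr(params, key) != value:
                raise ConfigurationError(
                    f"preset {name!r} field {key}={getattr(params, key)} does not "
                    f"match the published value {value}"
                )
    return calibrate(params) if calibrated else params
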