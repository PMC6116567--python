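import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neocirc.errors import (
    CalibrationError,
    ConfigurationError,
    DomainBoundError,
    OxygenSupplyExhaustedError,
    SteadyStateError,
)
from neocirc.model_core import (
    InstantaneousInputs,
    ModelState,
    ParameterSet,
    baseline_inputs,
    baseline_state,
    calibrate,
    derived_quantities,
    haemoglobin_to_haem_mM,
    load_preset,
    model_rhs,
    steady_state,
    subject_overrides,
)

PRETERM_TABLE = dict(
    CBF_n=19.8, CCO_tis=2.2, CuA_frac_n=0.67, CMRO2_n=40.865,
    P_a_n=30.0, Hbtot=9.75, V_blood_n=0.0233, P_ic_n=5.1,
)
ADULT_TABLE = dict(
    CBF_n=49.0, CCO_tis=5.5, CuA_frac_n=0.8, CMRO2_n=155.0,
    P_a_n=100.0, Hbtot=9.1, V_blood_n=0.04, P_ic_n=9.5,
)


class TestPresets:
    @pytest.mark.parametrize(
        "name,table", [("preterm", PRETERM_TABLE), ("adult", ADULT_TABLE)]
    )
    def test_population_presets_match_published_values(self, name, table):
        params = load_preset(name, calibrated=False)
        for key, value in table.items():
            assert getattr(params, key) == value

    @pytest.mark.parametrize("name", ["adult", "preterm", "neonate1", "neonate2"])
    def test_all_presets_calibrate(self, name):
        params = load_preset(name)
        assert params.is_calibrated
        assert 0 < params.OEF_n < 1

    def test_unknown_preset(self):
        with pytest.raises(KeyError):
            load_preset("piglet")


class TestCalibration:
    def test_baseline_is_exact_fixed_point_preterm(self, preterm):
        rhs = model_rhs(baseline_state(preterm), baseline_inputs(preterm), preterm)
        assert max(abs(v) for v in rhs) < 1e-10

    def test_baseline_is_exact_fixed_point_adult(self, adult):
        rhs = model_rhs(baseline_state(adult), baseline_inputs(adult), adult)
        assert max(abs(v) for v in rhs) < 1e-10

    def test_preterm_baseline_observables(self, preterm):
        dq = derived_quantities(baseline_state(preterm), baseline_inputs(preterm), preterm)
        assert dq.CBF == pytest.approx(19.8, rel=1e-12)
        assert dq.CMRO2 == pytest.approx(40.865, rel=1e-12)
        assert dq.V_blood == pytest.approx(0.0233, rel=1e-12)
        assert dq.oxCCO_tis == pytest.approx(0.67 * 2.2, rel=1e-12)

    def test_adult_baseline_cmro2(self, adult):
        dq = derived_quantities(baseline_state(adult), baseline_inputs(adult), adult)
        assert dq.CMRO2 == pytest.approx(155.0, rel=1e-12)

    def test_calibration_absorbs_hbtot_scaling(self, preterm):
        scaled = calibrate(preterm.replace(Hbtot=preterm.Hbtot * 1.1))
        rhs = model_rhs(baseline_state(scaled), baseline_inputs(scaled), scaled)
        assert max(abs(v) for v in rhs) < 1e-10

    def test_infeasible_extraction_raises(self, preterm):
        bad = preterm.replace(CMRO2_n=preterm.CBF_n * preterm.Hbtot * 2.0)
        with pytest.raises(CalibrationError):
            calibrate(bad)

    @settings(max_examples=25, deadline=None)
    @given(
        cbf=st.floats(10.0, 80.0),
        hb=st.floats(5.0, 14.0),
        cmro2_frac=st.floats(0.05, 0.8),
    )
    def test_fixed_point_property_over_random_parameters(self, cbf, hb, cmro2_frac):
        # CMRO2 chosen as a feasible fraction of O2 delivery
        params = ParameterSet(
            CBF_n=cbf, CCO_tis=2.2, CuA_frac_n=0.67,
            CMRO2_n=cmro2_frac * cbf * hb * 0.96,
            P_a_n=30.0, Hbtot=hb, V_blood_n=0.0233, P_ic_n=5.1,
        )
        params = calibrate(params)
        rhs = model_rhs(baseline_state(params), baseline_inputs(params), params)
        assert max(abs(v) for v in rhs) < 1e-10


class TestRhs:
    def test_requires_calibration(self):
        raw = ParameterSet(**PRETERM_TABLE)
        with pytest.raises(ConfigurationError):
            model_rhs(ModelState(0.0, 0.024, 0.67), InstantaneousInputs(30, 0.96, 40), raw)

    def test_state_out_of_bounds_named(self, preterm):
        with pytest.raises(DomainBoundError, match="mu"):
            model_rhs(ModelState(1.5, 0.024, 0.67), baseline_inputs(preterm), preterm)
        with pytest.raises(DomainBoundError, match="O2t"):
            model_rhs(ModelState(0.0, -0.01, 0.67), baseline_inputs(preterm), preterm)

    def test_demand_reduces_oxidised_cua(self, preterm):
        inputs = dataclasses.replace(baseline_inputs(preterm), u=1.5)
        _, _, da = model_rhs(baseline_state(preterm), inputs, preterm)
        assert da < 0

    def test_pressure_rise_drives_constriction(self, preterm):
        inputs = dataclasses.replace(baseline_inputs(preterm), P_a=preterm.P_a_n + 10)
        dmu, _, _ = model_rhs(baseline_state(preterm), inputs, preterm)
        assert dmu > 0


class TestDerivedQuantities:
    def test_quartic_flow_law_exact_ratios(self, preterm):
        # freeze tone at baseline; scale radius through the modulation factor
        state = baseline_state(preterm)
        base = baseline_inputs(preterm)
        cbf = {}
        for scale in (0.5, 1.0, 2.0):
            inputs = dataclasses.replace(base, m=scale)
            # strict=False: at r/2 the flow cannot carry baseline demand and
            # the saturation floor would trip; only the flow law is under test
            cbf[scale] = derived_quantities(state, inputs, preterm, strict=False).CBF
        assert cbf[2.0] / cbf[1.0] == pytest.approx(16.0, rel=1e-12)
        assert cbf[0.5] / cbf[1.0] == pytest.approx(1.0 / 16.0, rel=1e-12)

    def test_doubled_radius_gives_sixteenfold_flow(self, preterm):
        state = baseline_state(preterm)
        dq = derived_quantities(state, dataclasses.replace(baseline_inputs(preterm), m=2.0), preterm)
        expected = 16.0 * preterm.K_flow * preterm.r_n ** 4 * (preterm.P_a_n - preterm.P_ic_n)
        assert dq.CBF == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("p_a", [15.0, 30.0, 55.0])
    def test_clamp_pins_cbf(self, preterm, p_a):
        inputs = dataclasses.replace(baseline_inputs(preterm, cbf_clamped=True), P_a=p_a)
        dq = derived_quantities(baseline_state(preterm), inputs, preterm)
        assert dq.CBF == preterm.CBF_n

    def test_hbt_additivity_exact(self, preterm):
        rng = np.random.default_rng(7)
        for _ in range(20):
            state = ModelState(
                mu=float(rng.uniform(-0.9, 0.9)),
                O2t=float(rng.uniform(0.005, 0.05)),
                a=float(rng.uniform(0.1, 0.9)),
            )
            inputs = dataclasses.replace(
                baseline_inputs(preterm),
                P_a=float(rng.uniform(20, 45)),
                u=float(rng.uniform(0.8, 1.5)),
            )
            dq = derived_quantities(state, inputs, preterm)
            assert dq.HbT_tis - dq.HbO2_tis - dq.HHb_tis == 0.0
            assert 0.0 <= dq.SvO2 <= inputs.SaO2

    def test_oxygen_exhaustion_raises(self, preterm):
        inputs = dataclasses.replace(baseline_inputs(preterm), P_a=5.6)
        with pytest.raises(OxygenSupplyExhaustedError):
            derived_quantities(baseline_state(preterm), inputs, preterm)


def _integrate_to_equilibrium(params, inputs, t_end=400.0):
    """Independent oracle: brute-force time integration to equilibrium."""
    from scipy.integrate import solve_ivp

    def rhs(_, y):
        state = ModelState(float(np.clip(y[0], -1, 1)), max(float(y[1]), 0.0), float(np.clip(y[2], 0, 1)))
        return model_rhs(state, inputs, params, strict=False)

    sol = solve_ivp(rhs, (0, t_end), baseline_state(params).as_array(),
                    method="LSODA", rtol=1e-10, atol=1e-12)
    assert sol.success
    return ModelState.from_array(sol.y[:, -1])


class TestSteadyState:
    def test_baseline_inputs_return_baseline(self, preterm):
        state = steady_state(preterm, baseline_inputs(preterm))
        assert state.mu == pytest.approx(0.0, abs=1e-9)
        assert state.O2t == pytest.approx(preterm.O2t_n, rel=1e-9)
        assert state.a == pytest.approx(preterm.CuA_frac_n, rel=1e-9)

    def test_pressure_passive_above_plateau(self, preterm):
        inputs = dataclasses.replace(baseline_inputs(preterm), P_a=60.0)
        state = steady_state(preterm, inputs)
        assert derived_quantities(state, inputs, preterm).CBF > preterm.CBF_n
        oracle = _integrate_to_equilibrium(preterm, inputs)
        assert state.as_array() == pytest.approx(oracle.as_array(), abs=1e-6)

    def test_demand_raises_cmro2(self, preterm):
        inputs = dataclasses.replace(baseline_inputs(preterm), u=1.2)
        state = steady_state(preterm, inputs)
        assert derived_quantities(state, inputs, preterm).CMRO2 > preterm.CMRO2_n
        oracle = _integrate_to_equilibrium(preterm, inputs)
        assert state.as_array() == pytest.approx(oracle.as_array(), abs=1e-6)

    def test_agrees_with_time_integration_on_random_inputs(self, preterm):
        rng = np.random.default_rng(11)
        for _ in range(5):
            inputs = dataclasses.replace(
                baseline_inputs(preterm),
                P_a=float(rng.uniform(22, 50)),
                u=float(rng.uniform(0.85, 1.6)),
                PaCO2=float(rng.uniform(35, 45)),
            )
            state = steady_state(preterm, inputs)
            oracle = _integrate_to_equilibrium(preterm, inputs)
            assert state.as_array() == pytest.approx(oracle.as_array(), abs=1e-6)

    def test_fick_consistency_at_steady_states(self, preterm):
        rng = np.random.default_rng(3)
        for _ in range(5):
            inputs = dataclasses.replace(
                baseline_inputs(preterm),
                P_a=float(rng.uniform(24, 45)),
                u=float(rng.uniform(0.9, 1.4)),
            )
            state = steady_state(preterm, inputs)
            dq = derived_quantities(state, inputs, preterm)
            delivery_minus_return = dq.CBF * preterm.Hbtot * (inputs.SaO2 - dq.SvO2)
            assert delivery_minus_return == pytest.approx(dq.CMRO2, rel=1e-6)

    def test_svo2_monotone_in_cmro2_and_cbf(self, preterm):
        grid = {}
        for f_cmro2 in (0.9, 1.0, 1.1):
            for f_cbf in (0.9, 1.0, 1.1):
                p = calibrate(
                    preterm.replace(
                        CMRO2_n=preterm.CMRO2_n * f_cmro2,
                        CBF_n=preterm.CBF_n * f_cbf,
                    )
                )
                inputs = baseline_inputs(p)
                state = steady_state(p, inputs)
                grid[(f_cmro2, f_cbf)] = derived_quantities(state, inputs, p).SvO2
        for f_cbf in (0.9, 1.0, 1.1):
            assert grid[(0.9, f_cbf)] > grid[(1.0, f_cbf)] > grid[(1.1, f_cbf)]
        for f_cmro2 in (0.9, 1.0, 1.1):
            assert grid[(f_cmro2, 0.9)] < grid[(f_cmro2, 1.0)] < grid[(f_cmro2, 1.1)]

    def test_unsolvable_inputs_raise(self, preterm):
        inputs = dataclasses.replace(baseline_inputs(preterm), P_a=5.2)
        with pytest.raises((SteadyStateError, OxygenSupplyExhaustedError)):
            steady_state(preterm, inputs)


class TestSubjectOverrides:
    def test_neonate1_haemoglobin_conversion(self, preterm):
        p = subject_overrides(preterm, haemoglobin_g_dL=17.08, baseline_SpO2=0.95)
        assert p.Hbtot == pytest.approx(10.59, abs=0.01)
        assert p.SaO2_n == 0.95
        assert p.is_calibrated

    def test_neonate2_haemoglobin_conversion(self, preterm):
        p = subject_overrides(preterm, haemoglobin_g_dL=9.70)
        assert p.Hbtot == pytest.approx(6.02, abs=0.01)

    def test_identity_when_no_overrides(self, preterm):
        assert subject_overrides(preterm) is preterm

    def test_conversion_formula(self):
        assert haemoglobin_to_haem_mM(17.08) == pytest.approx(
            17.08 * 10.0 / 64500.0 * 4.0 * 1000.0, rel=1e-15
        )

    @pytest.mark.parametrize("kwargs", [dict(haemoglobin_g_dL=-1.0), dict(baseline_SpO2=1.2)])
    def test_out_of_range_rejected(self, preterm, kwargs):
        with pytest.raises(DomainBoundError):
            subject_overrides(preterm, **kwargs)


class TestParameterValidation:
    def test_negative_concentration_rejected(self):
        with pytest.raises(DomainBoundError):
            ParameterSet(**{**PRETERM_TABLE, "Hbtot": -1.0})

    def test_fraction_above_one_rejected(self):
        with pytest.raises(DomainBoundError):
            ParameterSet(**{**PRETERM_TABLE, "CuA_frac_n": 1.3})

    def test_pressure_ordering_enforced(self):
        with pytest.raises(DomainBoundError):
            ParameterSet(**{**PRETERM_TABLE, "P_ic_n": 40.0})
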