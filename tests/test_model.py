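import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mlautapse as m
from mlautapse.model import jacobian, ml_vector_field, recovery_time_constant


class TestPresets:
    def test_excitability_classes_differ_only_in_beta_w(self, type2, type3):
        assert type2.beta_w == -13.0
        assert type3.beta_w == -25.0
        shared = dict(C=2.0, g_Na=20.0, g_K=20.0, g_L=2.0, E_Na=50.0,
                      E_K=-100.0, E_L=-70.0, beta_m=-1.2, gamma_m=18.0,
                      gamma_w=10.0, phi_w=0.15)
        for p in (type2, type3):
            for key, val in shared.items():
                assert getattr(p, key) == val

    @pytest.mark.parametrize("bad", [dict(C=0.0), dict(gamma_w=-1.0), dict(phi_w=0.0)])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            m.ModelParams(**bad)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError):
            m.preset("typeI")


class TestGating:
    def test_half_activation_and_slope_point(self):
        assert m.boltzmann_activation(-13.0, -13.0, 10.0) == pytest.approx(0.5)
        # one slope unit above half-activation: 0.5 (1 + tanh 1)
        assert m.boltzmann_activation(-3.0, -13.0, 10.0) == pytest.approx(0.88080, abs=1e-5)

    def test_saturation_limits(self):
        assert m.boltzmann_activation(1e3, 0.0, 10.0) == pytest.approx(1.0)
        assert m.boltzmann_activation(-1e3, 0.0, 10.0) == pytest.approx(0.0)

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError):
            m.boltzmann_activation(0.0, 0.0, 0.0)

    @settings(derandomize=True, max_examples=50)
    @given(v1=st.floats(-120, 60), dv=st.floats(1e-6, 50))
    def test_monotone_increasing(self, v1, dv):
        assert m.boltzmann_activation(v1 + dv, -13.0, 10.0) > m.boltzmann_activation(v1, -13.0, 10.0)


class TestRecoveryTimeConstant:
    def test_maximum_at_half_activation(self, type2):
        for variant in ("factor_2", "no_factor_2"):
            assert recovery_time_constant(type2.beta_w, type2, variant) == pytest.approx(1.0)

    def test_variant_values_one_slope_unit_away(self, type2):
        V = type2.beta_w + type2.gamma_w
        assert recovery_time_constant(V, type2, "no_factor_2") == pytest.approx(1 / np.cosh(1.0), abs=1e-5)
        assert recovery_time_constant(V, type2, "factor_2") == pytest.approx(1 / np.cosh(0.5), abs=1e-5)

    @settings(derandomize=True, max_examples=50)
    @given(x=st.floats(0, 80))
    def test_even_symmetry_and_bounds(self, x, type2):
        lo = recovery_time_constant(type2.beta_w - x, type2)
        hi = recovery_time_constant(type2.beta_w + x, type2)
        assert lo == pytest.approx(hi, rel=1e-12)
        assert 0 < lo <= 1


class TestVectorField:
    def test_independent_arithmetic_at_origin(self, type2):
        # dV at (V=0, w=0, I=0) assembled from the gating function directly
        m_act = m.boltzmann_activation(0.0, type2.beta_m, type2.gamma_m)
        expected = (-20.0 * m_act * (0.0 - 50.0) - 2.0 * (0.0 + 70.0)) / 2.0
        dV, _ = ml_vector_field(m.State(0.0, 0.0), 0.0, type2)
        assert dV == pytest.approx(expected, rel=1e-12)

    def test_w_nullcline_zeroes_dw(self, type2):
        for V in (-60.0, -20.0, 10.0):
            _, dw = ml_vector_field(m.State(V, float(m.w_inf(V, type2))), 0.0, type2)
            assert dw == pytest.approx(0.0, abs=1e-14)

    def test_vanishes_at_solved_equilibrium(self, type2):
        eq = m.find_equilibrium(30.0, type2)
        dV, dw = ml_vector_field(m.State(eq.V, eq.w), 30.0, type2)
        assert abs(dV) < 1e-10 and abs(dw) < 1e-10

    def test_non_finite_state_rejected(self, type2):
        with pytest.raises(ValueError):
            ml_vector_field(m.State(np.nan, 0.0), 0.0, type2)


class TestVNullcline:
    def test_passes_through_equilibrium(self, type2):
        eq = m.find_equilibrium(0.0, type2)
        assert m.v_nullcline(eq.V, 0.0, type2) == pytest.approx(float(m.w_inf(eq.V, type2)), abs=1e-10)

    def test_moves_up_with_applied_current(self, type2):
        assert m.v_nullcline(-20.0, 100.0, type2) > m.v_nullcline(-20.0, 0.0, type2)

    def test_singular_at_potassium_reversal(self, type2):
        with pytest.raises(ValueError):
            m.v_nullcline(type2.E_K, 0.0, type2)


def test_jacobian_matches_finite_differences(type2, type3):
    eps = 1e-6
    for params in (type2, type3):
        for (V, w, I) in [(-60.0, 0.01, 0.0), (-20.0, 0.3, 60.0), (5.0, 0.5, 100.0)]:
            J = jacobian(V, w, params)
            for col, (dV_, dw_) in enumerate([(eps, 0.0), (0.0, eps)]):
                fp = ml_vector_field(m.State(V + dV_, w + dw_), I, params)
                fm = ml_vector_field(m.State(V - dV_, w - dw_), I, params)
                num = (np.asarray(fp) - np.asarray(fm)) / (2 * eps)
                assert np.allclose(J[:, col], num, rtol=1e-6, atol=1e-8)
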