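"""Unit tests for the model equations, forcing protocols and closed forms."""

import cmath
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import hopfbundle as hb

TWO_PI = 2 * math.pi


class TestParameters:
    def test_defaults_are_reference_set(self, params):
        assert (params.mu_c, params.omega, params.tau, params.gamma,
                params.alpha) == (20.0, TWO_PI, 10.0, 10.0, 3.0)
        assert params.beta == -1.0 - 0.5j

    @pytest.mark.parametrize(
        "bad",
        [
            {"mu_c": 0.0},
            {"mu_c": -1.0},
            {"tau": 0.0},
            {"b_real": 0.5},  # supercritical branch requires b' < 0
            {"b_real": 0.0},
            {"gamma": -1.0},
            {"alpha": -0.1},
        ],
    )
    def test_invariant_violations_rejected(self, bad):
        with pytest.raises(ValueError):
            hb.Parameters(**bad)

    def test_selftuning_condition_holds_at_defaults(self, params):
        # quiescence reachable (mu_c < tau*alpha) and the resting fixed
        # point on the oscillatory side (alpha*tau/2 < mu_c)
        assert params.mu_c < params.tau * params.alpha
        fp = hb.selftuning_fixed_point(params, 0.0)
        assert fp == pytest.approx(-15.0)
        assert fp > -params.mu_c


class TestAdditiveForcing:
    @pytest.mark.parametrize(
        "t, expected",
        [(30.0, 1000 + 0j), (60.0, 0j), (10.0, 1000 + 0j), (50.0, 0j), (9.999, 0j)],
    )
    def test_boxcar_halfopen_window(self, t, expected):
        f = hb.AdditiveForcing.boxcar(1000.0, 10.0, 50.0)
        assert f(t) == expected

    def test_sinusoid_is_complex_rotating_tone(self):
        f = hb.AdditiveForcing.sinusoid(1.0, 8 * math.pi / 5)
        assert f(0.0) == 1 + 0j
        t = 0.37
        assert f(t) == pytest.approx(cmath.exp(1j * 8 * math.pi / 5 * t))

    def test_none_and_bad_windows(self):
        assert hb.AdditiveForcing.none()(123.4) == 0j
        with pytest.raises(ValueError):
            hb.AdditiveForcing.boxcar(1.0, 5.0, 5.0)


class TestParametricForcing:
    def test_rectangular_value_and_activity(self):
        f = hb.ParametricForcing.rectangular(1.0, 20.0, 0.0, 10.0)
        assert f(5.0) == (-19.0, True)
        assert f(15.0) == (0.0, False)
        assert hb.ParametricForcing.none()(3.0) == (0.0, False)

    def test_activity_iff_nonzero_value(self):
        f = hb.ParametricForcing.rectangular(1.0, 20.0, 0.0, 10.0)
        for t in (-1.0, 0.0, 5.0, 9.999, 10.0, 50.0):
            value, active = f(t)
            assert active == (value != 0.0)

    def test_mu_p_equal_mu_c_rejected(self):
        with pytest.raises(ValueError):
            hb.ParametricForcing.rectangular(20.0, 20.0, 0.0, 10.0)
        with pytest.raises(ValueError):
            hb.ParametricForcing.constant(20.0, 20.0)

    def test_strength_is_inverse_mu_p(self):
        assert hb.ParametricForcing.constant(2.5, 20.0).strength == pytest.approx(0.4)
        with pytest.raises(ValueError):
            hb.ParametricForcing.constant(-1.0, 20.0).strength


class TestRhs:
    def test_origin_fixed_point(self, params):
        dz, dmu = hb.rhs(0j, 0.0, params)
        assert dz == 0j
        assert dmu == pytest.approx(-params.alpha / 2)  # logistic(0) = 1/2

    def test_hand_evaluated_example(self, params):
        # z=1, mu=-15: (20-15)*1 + i*2pi*1 + (-1-i/2)*1
        dz, dmu = hb.rhs(1 + 0j, -15.0, params)
        assert dz == pytest.approx(4 + 1j * (TWO_PI - 0.5))
        assert dmu == pytest.approx(1.5 - 3.0 / (1.0 + math.exp(-10.0)))

    def test_active_parametric_forcing_supplants_mu(self, params):
        # effective coefficient mu_c + Fp = mu_p = 1: pure rotation at the
        # suppressed steady amplitude
        dz, _ = hb.rhs(1 + 0j, -999.0, params, fp_value=-19.0, fp_active=True)
        assert dz == pytest.approx(1j * (TWO_PI - 0.5))

    def test_mu_dynamics_independent_of_parametric_forcing(self, params):
        _, dmu_off = hb.rhs(0.3 + 0.1j, -5.0, params)
        _, dmu_on = hb.rhs(0.3 + 0.1j, -5.0, params, fp_value=-19.0, fp_active=True)
        assert dmu_on == dmu_off

    def test_nonfinite_state_rejected(self, params):
        with pytest.raises(FloatingPointError):
            hb.rhs(complex(math.nan, 0.0), 0.0, params)

    @given(
        theta=st.floats(0, TWO_PI),
        re=st.floats(-3, 3),
        im=st.floats(-3, 3),
        mu=st.floats(-30, 5),
    )
    def test_rotational_equivariance_without_additive_forcing(self, theta, re, im, mu):
        """With Fa=0 the flow commutes with rotations of z (the mu equation
        is excluded: it senses the bundle position x directly)."""
        params = hb.Parameters()
        z = complex(re, im)
        rot = cmath.exp(1j * theta)
        dz, _ = hb.rhs(z, mu, params)
        dz_rot, _ = hb.rhs(z * rot, mu, params)
        assert dz_rot == pytest.approx(dz * rot, abs=1e-9)


class TestClosedForms:
    def test_amplitude_law(self, params):
        assert hb.steady_amplitude(params, -params.mu_c) == 0.0
        assert hb.steady_amplitude(params, -25.0) == 0.0
        assert hb.steady_amplitude(params, -15.0) == pytest.approx(math.sqrt(5))
        assert hb.steady_amplitude(params, -19.0) == pytest.approx(1.0)

    def test_amplitude_increasing_on_oscillatory_side(self, params):
        mus = np.linspace(-params.mu_c, 5.0, 40)
        amps = [hb.steady_amplitude(params, m) for m in mus]
        assert amps[0] == 0.0
        assert np.all(np.diff(amps) > 0)

    def test_frequency_law(self, params):
        assert hb.steady_frequency(params, 0.0) == params.omega
        assert hb.steady_frequency(params, math.sqrt(5)) == pytest.approx(TWO_PI - 2.5)
        iso = hb.Parameters(b_imag=0.0)
        assert hb.steady_frequency(iso, 7.3) == iso.omega  # isochronous

    def test_one_third_law_values(self, iso_params):
        assert hb.resonant_response_at_bifurcation(iso_params, 0.0) == 0.0
        assert hb.resonant_response_at_bifurcation(iso_params, 1.0) == pytest.approx(1.0)
        assert hb.resonant_response_at_bifurcation(iso_params, 8.0) == pytest.approx(2.0)

    @pytest.mark.parametrize("mu_p", [0.25, 0.5, 1.0, 2.5, 5.0])
    def test_parametric_predictions_consistent_with_frequency_law(self, params, mu_p):
        a, freq = hb.parametric_steady_predictions(params, mu_p)
        assert a == pytest.approx(math.sqrt(mu_p))
        assert freq == pytest.approx(hb.steady_frequency(params, a))

    def test_parametric_predictions_quiescent_side(self, params):
        assert hb.parametric_steady_predictions(params, 0.0) == (0.0, params.omega)
        assert hb.parametric_steady_predictions(params, -3.0) == (0.0, params.omega)

    def test_open_probability_limits(self):
        assert hb.open_probability(10.0, 0.0) == 0.5
        assert hb.open_probability(10.0, 1e4) == pytest.approx(1.0)
        assert hb.open_probability(10.0, -1e4) == pytest.approx(0.0, abs=1e-12)
        arr = hb.open_probability(10.0, np.array([-1e4, 0.0, 1e4]))
        assert arr == pytest.approx([0.0, 0.5, 1.0], abs=1e-12)

    def test_selftuning_fixed_point_limits(self, params):
        assert hb.selftuning_fixed_point(params, 1e4) == pytest.approx(-30.0)
        assert hb.selftuning_fixed_point(params, -1e4) == pytest.approx(0.0, abs=1e-9)
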