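"""Tests for trace statistics: phase, locking, spectra, widths, fits."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import hopfbundle as hb
from conftest import make_tone_trace

TWO_PI = 2 * math.pi


class TestAmplitudePhase:
    def test_pure_rotation(self):
        tr = make_tone_trace(amplitude=1.0, omega=TWO_PI)
        a, phi = hb.amplitude_phase(tr)
        assert a == pytest.approx(np.ones_like(a))
        freq = hb.instantaneous_frequency(tr)
        assert freq[5:-5] == pytest.approx(np.full_like(freq[5:-5], TWO_PI), rel=1e-6)

    def test_constant_real_state(self):
        t = np.arange(0.0, 10.0, 0.01)
        tr = hb.Trace(t, np.full_like(t, 2.0), np.zeros_like(t), np.zeros_like(t))
        a, phi = hb.amplitude_phase(tr)
        assert a == pytest.approx(np.full_like(a, 2.0))
        assert np.allclose(hb.instantaneous_frequency(tr), 0.0)

    def test_zero_amplitude_flagged_nan(self):
        t = np.arange(0.0, 1.0, 0.1)
        x = np.ones_like(t)
        x[3] = 0.0
        tr = hb.Trace(t, x, np.zeros_like(t), np.zeros_like(t))
        _, phi = hb.amplitude_phase(tr)
        assert math.isnan(phi[3]) and np.isfinite(phi[2])


class TestSteadyCycleStats:
    def test_pure_rotation_recovers_tone(self):
        tr = make_tone_trace(amplitude=1.0, omega=TWO_PI, t_end=80.0)
        a, f = hb.steady_cycle_stats(tr, 50)
        assert a == pytest.approx(1.0, rel=1e-9)
        assert f == pytest.approx(TWO_PI, rel=1e-6)

    def test_insufficient_cycles_rejected(self):
        tr = make_tone_trace(t_end=10.0)
        with pytest.raises(ValueError):
            hb.steady_cycle_stats(tr, 50)


class TestLockingStatistics:
    def test_perfectly_locked_phase_gives_unit_vector_strength(self):
        tr = make_tone_trace(amplitude=2.0, omega=5.0, phase0=0.7, t_end=40.0)
        assert hb.vector_strength(tr, 5.0) == pytest.approx(1.0, abs=1e-9)

    def test_uniformly_drifting_phase_gives_zero(self):
        # oscillator at omega, reference at omega': the difference sweeps
        # whole circles and the circular mean decays like the inverse
        # window length (sinc tail), ~1e-2 for this 60-unit window
        tr = make_tone_trace(omega=TWO_PI, t_end=100.0)
        assert hb.vector_strength(tr, 1.5 * TWO_PI) == pytest.approx(0.0, abs=0.02)

    def test_two_sample_antiphase_window(self):
        omega_p = TWO_PI  # one forcing period across the two samples
        t = np.array([0.0, 1.0])
        # phase differences 0 and pi: z phases 0 and omega_p*1 + pi
        tr = hb.Trace(t, np.array([1.0, -1.0]), np.array([0.0, 0.0]),
                      np.zeros(2))
        assert hb.vector_strength(tr, omega_p, window_fraction=1.0) == pytest.approx(0.0, abs=1e-12)

    def test_phase_locked_amplitude_normalisation(self):
        tr = make_tone_trace(amplitude=3.0, omega=4.0, t_end=60.0)
        assert hb.phase_locked_amplitude(tr, 4.0) == pytest.approx(3.0, rel=1e-6)

    def test_off_frequency_tone_rejected_by_projection(self):
        tr = make_tone_trace(amplitude=1.0, omega=4.0, t_end=200.0)
        assert hb.phase_locked_amplitude(tr, 9.0) < 0.01

    def test_window_shorter_than_one_period_rejected(self):
        tr = make_tone_trace(t_end=5.0)
        with pytest.raises(ValueError):
            hb.vector_strength(tr, 0.1)

    @given(theta=st.floats(0, TWO_PI))
    def test_global_phase_shift_invariance(self, theta):
        """Rotating the trace and the reference phase origin together
        leaves V and the locked amplitude unchanged."""
        base = make_tone_trace(amplitude=1.3, omega=5.0, t_end=40.0)
        shifted = make_tone_trace(amplitude=1.3, omega=5.0, phase0=theta, t_end=40.0)
        assert hb.vector_strength(shifted, 5.0) == pytest.approx(
            hb.vector_strength(base, 5.0), abs=1e-9
        )
        assert hb.phase_locked_amplitude(shifted, 5.0) == pytest.approx(
            hb.phase_locked_amplitude(base, 5.0), abs=1e-9
        )


class TestBartlettPsd:
    def test_constant_signal_power_in_dc_bin(self):
        psd = hb.bartlett_psd(np.full(1024, 3.0), 0.01, 8)
        assert psd.power.argmax() == 0
        assert psd.mean_square() == pytest.approx(9.0, rel=1e-9)

    def test_pure_tone_single_bin_and_parseval(self):
        dt = 0.01
        n = 4096
        t = np.arange(n) * dt
        nu = 25.0 / (n // 8 * dt)  # exact bin frequency for 8 segments
        x = np.sin(TWO_PI * nu * t)
        psd = hb.bartlett_psd(x, dt, 8)
        peak_omega = psd.omega[psd.power.argmax()]
        assert peak_omega == pytest.approx(TWO_PI * nu, rel=1e-9)
        assert psd.mean_square() == pytest.approx(0.5, rel=1e-9)

    def test_segmenting_preserves_peak_location(self):
        dt = 0.01
        t = np.arange(4096) * dt
        x = np.sin(TWO_PI * 12.5 * t)
        p1 = hb.bartlett_psd(x, dt, 1)
        p8 = hb.bartlett_psd(x, dt, 8)
        assert p1.omega[p1.power.argmax()] == pytest.approx(
            p8.omega[p8.power.argmax()], rel=1e-6
        )

    def test_parseval_identity_general_signal(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=4096)
        psd = hb.bartlett_psd(x, 0.02, 8)
        assert psd.mean_square() == pytest.approx(np.mean(x**2), rel=1e-9)

    def test_too_many_segments_rejected(self):
        with pytest.raises(ValueError):
            hb.bartlett_psd(np.ones(10), 0.1, 11)


class TestPowerRatio:
    @staticmethod
    def _spectrum(total, n=10):
        omega = np.linspace(1.0, 2.0, n)
        return hb.SpectrumEstimate(omega, np.full(n, total / n), 1, 1.0)

    def test_identical_spectra_give_one(self):
        s = self._spectrum(42.0)
        assert hb.power_ratio(s, s) == pytest.approx(1.0)

    @pytest.mark.parametrize("ti, tm, expected", [(100.0, 10.0, 2.0),
                                                  (10.0, 100.0, 0.5)])
    def test_ratio_of_logs_not_log_of_ratio(self, ti, tm, expected):
        r = hb.power_ratio(self._spectrum(ti), self._spectrum(tm))
        assert r == pytest.approx(expected)

    def test_unit_denominator_rejected(self):
        with pytest.raises(ValueError):
            hb.power_ratio(self._spectrum(10.0), self._spectrum(1.0))

    def test_mismatched_grids_rejected(self):
        a = self._spectrum(10.0, n=10)
        b = self._spectrum(10.0, n=11)
        with pytest.raises(ValueError):
            hb.power_ratio(a, b)


class TestHalfWidth:
    def test_symmetric_triangle(self):
        x = np.linspace(-2, 2, 401)
        y = np.clip(1 - np.abs(x), 0, None)
        assert hb.half_width(x, y) == pytest.approx(1.0, abs=1e-9)

    def test_lorentzian_closed_form(self):
        w = 0.7
        x = np.linspace(-8, 8, 2001)
        y = 1.0 / (1.0 + (x / w) ** 2)
        assert hb.half_width(x, y) == pytest.approx(2 * w, rel=1e-4)

    def test_monotone_curve_rejected(self):
        x = np.linspace(0, 1, 50)
        with pytest.raises(ValueError):
            hb.half_width(x, x)

    def test_uncrossed_side_rejected(self):
        x = np.linspace(-1, 1, 101)
        y = 1.0 - 0.3 * x**2  # max in the middle, never falls below half
        with pytest.raises(ValueError):
            hb.half_width(x, y)

    @given(scale=st.floats(1e-3, 1e3))
    def test_vertical_scaling_invariance(self, scale):
        x = np.linspace(-3, 3, 301)
        y = np.exp(-(x**2))
        assert hb.half_width(x, scale * y) == pytest.approx(
            hb.half_width(x, y), rel=1e-12
        )


class TestRecoveryTime:
    @staticmethod
    def _ramp_trace(t_stop=10.0, t_recover=22.5, t_end=60.0):
        """Amplitude decays to zero after t_stop, then regrows linearly,
        crossing 0.5*reference exactly at t_recover."""
        t = np.arange(0.0, t_end, 0.01)
        ref = 2.0
        a = np.where(t <= t_stop, ref,
                     np.where(t < t_stop + 2, 0.01,
                              np.minimum(ref, (t - (t_stop + 2)) / (t_recover - t_stop - 2))))
        return hb.Trace(t, a, np.zeros_like(t), np.zeros_like(t)), ref

    def test_crossing_time_by_construction(self):
        tr, ref = self._ramp_trace()
        tr_time = hb.recovery_time(tr, 10.0, 0.5, ref)
        assert tr_time == pytest.approx(12.5, abs=0.02)

    def test_never_recovered_sentinel(self):
        t = np.arange(0.0, 30.0, 0.01)
        a = np.where(t <= 5.0, 2.0, 0.01)
        tr = hb.Trace(t, a, np.zeros_like(t), np.zeros_like(t))
        assert hb.recovery_time(tr, 5.0, 0.5, 2.0) == hb.NOT_RECOVERED

    def test_never_quiescent_gives_zero(self):
        tr = make_tone_trace(amplitude=2.0, t_end=30.0)
        assert hb.recovery_time(tr, 5.0, 0.5, 2.0) == 0.0

    def test_monotone_in_threshold_fraction(self):
        tr, ref = self._ramp_trace()
        fracs = [0.2, 0.4, 0.6, 0.8]
        times = [hb.recovery_time(tr, 10.0, f, ref) for f in fracs]
        assert all(t2 >= t1 for t1, t2 in zip(times, times[1:]))

    def test_mu_crossing_time(self):
        t = np.arange(0.0, 40.0, 0.01)
        mu = -30.0 + 0.5 * t  # crosses -20 at t=20
        tr = hb.Trace(t, np.ones_like(t), np.zeros_like(t), mu)
        assert hb.mu_crossing_time(tr, 5.0, -20.0) == pytest.approx(15.0, abs=0.02)


class TestFitRelation:
    def test_power_law_exact(self):
        x = np.logspace(0, 1, 12)
        fit = hb.fit_relation(x, x ** (1 / 3), "power_law")
        assert fit.coefficients[1] == pytest.approx(1 / 3, abs=1e-12)

    def test_offset_power_exact(self):
        x = np.geomspace(0.1, 5, 15)
        fit = hb.fit_relation(x, -0.095 + x ** (-0.54), "offset_power")
        assert fit.coefficients == pytest.approx((-0.095, -0.54), abs=1e-8)

    def test_log10_linear_exact(self):
        x = np.logspace(-2, 1, 10)
        fit = hb.fit_relation(x, 1.0 - 0.019 * np.log10(x), "log10_linear")
        assert fit.coefficients == pytest.approx((1.0, -0.019), abs=1e-12)

    @given(
        c=st.floats(0.1, 10),
        b=st.floats(-2, 2),
    )
    def test_power_law_random_coefficients(self, c, b):
        x = np.logspace(-1, 1, 9)
        fit = hb.fit_relation(x, c * x**b, "power_law")
        assert fit.coefficients[0] == pytest.approx(c, rel=1e-8)
        assert fit.coefficients[1] == pytest.approx(b, abs=1e-8)

    def test_nonpositive_data_rejected(self):
        with pytest.raises(ValueError):
            hb.fit_relation([1, 2, 3], [1, -1, 1], "power_law")
        with pytest.raises(ValueError):
            hb.fit_relation([-1, 2, 3], [1, 1, 1], "log10_linear")
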