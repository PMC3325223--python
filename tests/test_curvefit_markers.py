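"""Fourier, skewed-cosine and NOSA fits and their derived phase markers."""

import math

import numpy as np
import pytest

from melaphase.profile_core import SampleSeries, PMOL_PER_L
from melaphase.curvefit_markers import (
    HarmonicFit,
    adjusted_r2,
    curve_markers,
    fit_fourier,
    fit_skewed,
    nosa_fit,
    skewed_eval,
)


def _series(times, concs):
    return SampleSeries("A", 1, np.asarray(times, float),
                        np.asarray(concs, float), PMOL_PER_L)


def _grid(step=0.5):
    return np.arange(12.0, 36.0, step)


class TestFourier:
    def test_exact_linear_model_recovered(self):
        t = _grid()
        c = 40 + 25 * np.cos(2 * np.pi * t / 24) - 10 * np.sin(2 * np.pi * t / 24)
        fit = fit_fourier(_series(t, np.maximum(c, 0)), K=2)
        # keep the signal non-negative: 40 - sqrt(25^2+10^2) > 0, no clipping
        assert fit.converged
        assert fit.residual_ss < 1e-16
        assert fit.mesor == pytest.approx(40, abs=1e-8)
        assert fit.cos_coef[0] == pytest.approx(25, abs=1e-8)
        assert fit.sin_coef[0] == pytest.approx(-10, abs=1e-8)
        assert fit.cos_coef[1] == pytest.approx(0, abs=1e-8)

    def test_constant_series_projects_to_mesor(self):
        t = _grid()
        fit = fit_fourier(_series(t, np.full_like(t, 7.0)), K=2)
        assert fit.mesor == pytest.approx(7.0)
        np.testing.assert_allclose(fit.cos_coef, 0, atol=1e-10)
        np.testing.assert_allclose(fit.sin_coef, 0, atol=1e-10)

    def test_k3_on_k2_data_has_null_third_harmonic(self):
        t = _grid()
        c = 50 + 20 * np.cos(2 * np.pi * t / 24) + 5 * np.sin(4 * np.pi * t / 24)
        fit = fit_fourier(_series(t, c), K=3)
        assert abs(fit.cos_coef[2]) < 1e-10
        assert abs(fit.sin_coef[2]) < 1e-10

    def test_nested_models_residual_ordering(self, noisy_day):
        f2 = fit_fourier(noisy_day, K=2)
        f3 = fit_fourier(noisy_day, K=3)
        assert f3.residual_ss <= f2.residual_ss + 1e-9


class TestAdjustedR2:
    def test_perfect_fit(self):
        assert adjusted_r2(0.0, 100.0, 25, 5) == 1.0

    def test_chance_level_fit(self):
        assert adjusted_r2(100.0, 100.0, 25, 5) == pytest.approx(1 - 24 / 19)

    def test_parameter_penalty_is_monotone(self):
        scores = [adjusted_r2(30.0, 100.0, 25, p) for p in (3, 5, 7, 9)]
        assert all(a > b for a, b in zip(scores, scores[1:]))

    def test_needs_spare_degrees_of_freedom(self):
        with pytest.raises(ValueError):
            adjusted_r2(1.0, 2.0, 6, 5)


class TestSkewed:
    def test_self_consistency_recovery(self):
        t = _grid()
        truth = dict(baseline=3.0, amplitude=95.0, phase_h=26.0, skew=0.35,
                     bimodality=-0.1, nu=1.8)
        c = skewed_eval(t, truth["baseline"], truth["amplitude"], truth["phase_h"],
                        truth["skew"], truth["bimodality"], truth["nu"])
        fit = fit_skewed(_series(t, c))
        assert fit.converged
        assert fit.adjusted_r2 > 0.999
        assert fit.phase_h % 24 == pytest.approx(truth["phase_h"] % 24, abs=0.05)
        assert fit.amplitude == pytest.approx(truth["amplitude"], rel=0.02)

    def test_reduced_form_is_symmetric_about_peak(self):
        # skew = bimodality = 0, nu = 1 is a clipped cosine: crossings sit
        # symmetrically around the peak
        t = _grid()
        c = skewed_eval(t, 0.0, 80.0, 24.0, 0.0, 0.0, 1.0)
        fit = fit_skewed(_series(t, c))
        mk = curve_markers(fit, (12.0, 36.0))
        up, down = mk["SkewedUpcross"].phase_h, mk["SkewedDowncross"].phase_h
        assert (up + down) / 2 == pytest.approx(24.0, abs=0.02)

    def test_flat_series_recorded_not_crashed(self):
        t = _grid()
        fit = fit_skewed(_series(t, np.full_like(t, 2.0)))
        # either the optimiser reports failure or the fitted pulse is null
        assert (not fit.converged) or fit.amplitude == pytest.approx(0.0, abs=1e-6)


class TestCurveMarkers:
    def test_cosine_closed_form(self):
        # 50 + 50 cos(2pi (t-26)/24): max 100 at 26, half-max 50 at 20 and 32
        w = 2 * np.pi / 24
        fit = HarmonicFit(50.0, np.array([50 * np.cos(w * 26), 0.0]),
                          np.array([50 * np.sin(w * 26), 0.0]), 24.0, 0.0, 5,
                          1.0, True)
        mk = curve_markers(fit, (14.0, 38.0))
        assert mk["F2Max"].phase_h == pytest.approx(26.0, abs=1 / 60)
        assert mk["F2Upcross"].phase_h == pytest.approx(20.0, abs=1e-3)
        assert mk["F2Downcross"].phase_h == pytest.approx(32.0, abs=1e-3)

    def test_two_equal_peaks_tie_break_earliest(self):
        # pure second harmonic: peaks 12 h apart, equal height
        fit = HarmonicFit(10.0, np.array([0.0, 8.0]), np.array([0.0, 0.0]),
                          24.0, 0.0, 5, 1.0, True)
        mk = curve_markers(fit, (0.0, 24.0))
        assert mk["F2Max"].phase_h == pytest.approx(0.0, abs=1e-9)

    def test_upcross_before_max_before_downcross(self, noisy_day):
        for K in (2, 3):
            fit = fit_fourier(noisy_day, K=K)
            mk = curve_markers(fit, (float(noisy_day.times[0]),
                                     float(noisy_day.times[0]) + 24.0))
            assert (mk[f"F{K}Upcross"].phase_h < mk[f"F{K}Max"].phase_h
                    < mk[f"F{K}Downcross"].phase_h)

    def test_time_translation_equivariance(self, noisy_day):
        s = noisy_day
        delta = 5.25
        shifted = _series(s.times + delta, s.concentrations)
        w0 = (float(s.times[0]), float(s.times[0]) + 24.0)
        w1 = (w0[0] + delta, w0[1] + delta)
        for K in (2, 3):
            a = curve_markers(fit_fourier(s, K=K), w0)
            b = curve_markers(fit_fourier(shifted, K=K), w1)
            for name in a:
                assert b[f"{name}"].phase_h == pytest.approx(
                    a[name].phase_h + delta, abs=1e-6)

    def test_f3_and_f2_upcross_agree_on_clean_pulse(self, noiseless_subject):
        days, _ = noiseless_subject
        s = days[0]
        w = (float(s.times[0]), float(s.times[0]) + 24.0)
        up2 = curve_markers(fit_fourier(s, K=2), w)["F2Upcross"].phase_h
        up3 = curve_markers(fit_fourier(s, K=3), w)["F3Upcross"].phase_h
        assert abs(up3 - up2) < 0.9


class TestNosa:
    def test_period_and_amplitude_recovery(self):
        t = _grid()
        c = 60 + 30 * np.cos(2 * np.pi * (t - 26) / 24.15)
        fit = nosa_fit(_series(t, c))
        assert fit.period_h == pytest.approx(24.15, abs=0.011)
        assert fit.amplitude == pytest.approx(30.0, abs=1e-5)

    def test_flat_series_amplitude_zero(self):
        t = _grid()
        fit = nosa_fit(_series(t, np.full_like(t, 9.0)))
        assert fit.amplitude == pytest.approx(0.0, abs=1e-9)

    def test_amplitude_invariant_to_mesor_shift(self, noisy_day):
        s = noisy_day
        shifted = _series(s.times, s.concentrations + 55.0)
        a = nosa_fit(s)
        b = nosa_fit(shifted)
        assert b.amplitude == pytest.approx(a.amplitude, rel=1e-9)
        assert b.fit_peak == pytest.approx(a.fit_peak + 55.0, rel=1e-9)
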