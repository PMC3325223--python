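"""Two-compartment differential-equation model: simulation and fitting."""

import math

import numpy as np
import pytest

from melaphase.profile_core import SampleSeries, PMOL_PER_L
from melaphase.physio_model import (
    PhysioParams,
    fit_physio,
    simulate,
    simulate_analytic,
    synthesis_rate,
)
from melaphase.synthetic_data import SubjectScenario, simulate_subject

P_REF = PhysioParams(t_on=21.5, t_off=31.5, A=100.0, alpha=1.5, delta=1.4,
                     beta_I=1.2, beta_C=0.92, b=2.5, H2_0=0.0)


def two_exp_oracle(t, t_on, t_off, A, beta_I, beta_C, H2_0=0.0):
    """Independent closed form for *piecewise-constant* synthesis (the
    alpha, delta -> infinity limit): u = A on [t_on, t_off), else 0.

    Derived by elementary integration of the cascade with constant forcing:
    H1 relaxes to A/beta_I, H2 to A/beta_C, each as explicit one- and
    two-exponential expressions.  Written from scratch as the oracle; shares
    no code with the solver under test.
    """
    t = np.asarray(t, dtype=float)

    def seg_const(h1_0, h2_0, u, s):
        # H1(s) with constant forcing u
        h1 = u / beta_I + (h1_0 - u / beta_I) * np.exp(-beta_I * s)
        # H2(s) = particular(const) + response to each H1 exponential
        c_inf = u / beta_C
        k1 = beta_I * (h1_0 - u / beta_I) / (beta_C - beta_I)
        k2 = h2_0 - c_inf - k1
        h2 = c_inf + k1 * np.exp(-beta_I * s) + k2 * np.exp(-beta_C * s)
        return h1, h2

    out = np.empty_like(t)
    t0 = t[0]
    state = (0.0, H2_0)
    bps = [t0] + [x for x in (t_on, t_off) if t0 < x < t[-1]] + [t[-1]]
    for ta, tb in zip(bps[:-1], bps[1:]):
        u = A if (ta >= t_on and ta < t_off) else 0.0
        sel = (t >= ta) & ((t <= tb) if tb == t[-1] else (t < tb))
        _, h2 = seg_const(*state, u, t[sel] - ta)
        out[sel] = h2
        state = tuple(x[-1] for x in seg_const(*state, u, np.array([tb - ta])))
    return out


class TestSynthesisRate:
    def test_continuous_and_zero_at_onset(self):
        eps = 1e-9
        assert synthesis_rate(P_REF.t_on + eps, P_REF) == pytest.approx(0.0, abs=1e-6)
        assert synthesis_rate(P_REF.t_on - eps, P_REF) == 0.0

    def test_saturates_to_A(self):
        p = PhysioParams(10.0, 22.0, 100.0, 50.0, 1.0, 1.0, 0.9, 0.0, 0.0)
        assert synthesis_rate(22.0 - 1e-9, p) == pytest.approx(100.0, rel=1e-6)

    def test_nonnegative_everywhere(self):
        t = np.linspace(0, 48, 1000)
        assert np.all(synthesis_rate(t, P_REF) >= 0)

    def test_continuous_at_offset(self):
        lo = synthesis_rate(P_REF.t_off - 1e-9, P_REF)
        hi = synthesis_rate(P_REF.t_off + 1e-9, P_REF)
        assert hi == pytest.approx(lo, rel=1e-6)


class TestSimulate:
    def test_zero_synthesis_is_homogeneous_decay(self):
        p = PhysioParams(40.0, 50.0, 0.0, 1.5, 1.4, 1.2, 0.92, 3.0, 20.0)
        t = np.arange(0.0, 30.0, 0.5)
        y = simulate(p, t)
        expected = 3.0 + 20.0 * np.exp(-0.92 * t)
        np.testing.assert_allclose(y, expected, rtol=1e-6, atol=1e-8)

    def test_linear_in_A(self):
        t = np.arange(12.0, 38.0, 0.25)
        base = simulate_analytic(PhysioParams(21.5, 31.5, 0.0, 1.5, 1.4,
                                              1.2, 0.92, 2.5, 8.0), t)
        y1 = simulate_analytic(PhysioParams(21.5, 31.5, 100.0, 1.5, 1.4, 1.2,
                                            0.92, 2.5, 8.0), t)
        y2 = simulate_analytic(PhysioParams(21.5, 31.5, 200.0, 1.5, 1.4, 1.2,
                                            0.92, 2.5, 8.0), t)
        np.testing.assert_allclose(y2 - base, 2.0 * (y1 - base), rtol=1e-9,
                                   atol=1e-9)

    def test_numeric_matches_analytic(self):
        t = np.arange(10.0, 40.0, 0.1)
        ya = simulate_analytic(P_REF, t)
        yn = simulate(P_REF, t)
        np.testing.assert_allclose(yn, ya, rtol=1e-6)

    def test_square_synthesis_limit_matches_independent_oracle(self):
        # alpha, delta large: the ramp/decay drive approaches the on/off
        # pulse, with limit error O(A/alpha)
        big = 1e7
        p = PhysioParams(20.0, 30.0, 80.0, big, big, 1.2, 0.92, 0.0, 5.0)
        t = np.arange(10.0, 40.0, 0.25)
        oracle = two_exp_oracle(t, 20.0, 30.0, 80.0, 1.2, 0.92, H2_0=5.0)
        ya = simulate_analytic(p, t)
        np.testing.assert_allclose(ya, oracle, rtol=1e-6, atol=1e-6)
        yn = simulate(p, t)
        np.testing.assert_allclose(yn, oracle, rtol=1e-6, atol=1e-5)

    def test_analytic_handles_coincident_rates(self):
        # beta_I == beta_C triggers the deterministic nudge, not a blow-up
        p = PhysioParams(21.5, 31.5, 100.0, 1.5, 1.4, 0.9, 0.9, 2.5, 0.0)
        t = np.arange(12.0, 38.0, 0.5)
        y = simulate_analytic(p, t)
        assert np.all(np.isfinite(y))
        np.testing.assert_allclose(simulate(p, t), y, rtol=1e-5)


class TestFitPhysio:
    def test_noiseless_recovery(self):
        days, truth = simulate_subject(
            SubjectScenario(noise_cv=0.0, n_days=1, seed=3, subject_id="T"))
        fit = fit_physio(days[0])
        assert fit.converged
        assert fit.syn_on == pytest.approx(truth["syn_on"][0], abs=0.05)
        assert fit.syn_off == pytest.approx(truth["syn_off"][0], abs=0.1)
        assert fit.adjusted_r2 > 0.9999

    def test_time_translation_equivariance(self):
        days, _ = simulate_subject(
            SubjectScenario(noise_cv=0.0, n_days=1, seed=3, subject_id="T"))
        s = days[0]
        delta = 7.75
        shifted = SampleSeries(s.subject_id, 1, s.times + delta,
                               s.concentrations, PMOL_PER_L)
        a, b = fit_physio(s), fit_physio(shifted)
        assert b.syn_on == pytest.approx(a.syn_on + delta, abs=1e-3)
        assert b.syn_off == pytest.approx(a.syn_off + delta, abs=1e-3)

    def test_concentration_scale_equivariance(self):
        days, _ = simulate_subject(
            SubjectScenario(noise_cv=0.0, n_days=1, seed=3, subject_id="T"))
        s = days[0]
        scale = 2.5
        scaled = SampleSeries(s.subject_id, 1, s.times,
                              s.concentrations * scale, PMOL_PER_L)
        a, b = fit_physio(s), fit_physio(scaled)
        assert b.syn_on == pytest.approx(a.syn_on, abs=1e-3)
        assert b.params.A == pytest.approx(a.params.A * scale, rel=1e-2)
        assert b.params.b == pytest.approx(a.params.b * scale, rel=1e-2, abs=1e-3)
        assert b.params.beta_C == pytest.approx(a.params.beta_C, rel=1e-3)

    def test_flat_profile_recorded_not_fit(self):
        t = np.arange(14.0, 38.0, 0.5)
        s = SampleSeries("flat", 1, t, np.full_like(t, 2.5), PMOL_PER_L)
        fit = fit_physio(s)
        assert not fit.converged
        assert fit.note != ""
        with pytest.raises(ValueError):
            _ = fit.syn_on

    def test_too_few_samples_is_an_error(self):
        t = np.arange(0.0, 5.0, 0.5)
        s = SampleSeries("x", 1, t, np.ones_like(t), PMOL_PER_L)
        with pytest.raises(ValueError):
            fit_physio(s)


class TestParamValidation:
    def test_onset_must_precede_offset(self):
        with pytest.raises(ValueError):
            PhysioParams(30.0, 20.0, 1.0, 1.0, 1.0, 1.0, 1.0, 0.0, 0.0)

    def test_rates_positive(self):
        with pytest.raises(ValueError):
            PhysioParams(20.0, 30.0, 1.0, 0.0, 1.0, 1.0, 1.0, 0.0, 0.0)
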