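import numpy as np
import pytest

from curemix import (
    NonConvergenceError,
    SimulationConfig,
    SurvivalSample,
    fit_cox_ph,
    fit_logistic_on_delta,
    generate_cure_sample,
)
from curemix.naive import breslow_baseline

from conftest import two_by_two_sample


class TestLogisticOnDelta:
    def test_binary_covariate_equals_log_odds_ratio(self):
        s = two_by_two_sample(100, 10, 100, 20)
        fit = fit_logistic_on_delta(s)
        expect = np.log(20 / 80) - np.log(10 / 90)
        assert fit.coef[1] == pytest.approx(expect, abs=1e-8)
        assert fit.coef[1] == pytest.approx(0.8109, abs=1e-4)
        assert fit.converged

    def test_equal_stratum_fractions_give_zero_slope(self):
        s = two_by_two_sample(120, 30, 80, 20)
        assert fit_logistic_on_delta(s).coef[1] == pytest.approx(0.0, abs=1e-8)

    def test_continuous_covariate_matches_grid_search(self):
        x = np.array([-1.2, -0.4, 0.1, 0.6, 1.3, 2.0])
        event = np.array([0, 0, 1, 0, 1, 1])
        s = SurvivalSample(ids=np.arange(6), time=np.ones(6) + np.arange(6),
                           event=event, x=x, z=np.empty((6, 0)), x_names=["w"])
        fit = fit_logistic_on_delta(s)

        def ll(b0, b1):
            eta = b0 + b1 * x
            return event @ eta - np.logaddexp(0, eta).sum()

        # coarse-to-fine grid maximisation of the Bernoulli likelihood
        b0g, b1g = np.meshgrid(np.linspace(-5, 5, 201), np.linspace(-5, 5, 201))
        vals = np.array([[ll(a, b) for a, b in zip(ra, rb)] for ra, rb in zip(b0g, b1g)])
        i, j = np.unravel_index(np.argmax(vals), vals.shape)
        c0, c1 = b0g[i, j], b1g[i, j]
        b0f, b1f = np.meshgrid(np.linspace(c0 - 0.1, c0 + 0.1, 201),
                               np.linspace(c1 - 0.1, c1 + 0.1, 201))
        vals = np.array([[ll(a, b) for a, b in zip(ra, rb)] for ra, rb in zip(b0f, b1f)])
        i, j = np.unravel_index(np.argmax(vals), vals.shape)
        assert fit.coef[0] == pytest.approx(b0f[i, j], abs=2e-3)
        assert fit.coef[1] == pytest.approx(b1f[i, j], abs=2e-3)

    def test_matches_statsmodels(self, design_sample):
        import statsmodels.api as sm

        sample, _ = design_sample
        fit = fit_logistic_on_delta(sample)
        X = sm.add_constant(sample.x)
        ref = sm.GLM(sample.event, X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(fit.coef, ref.params, atol=1e-6)
        np.testing.assert_allclose(fit.se, ref.bse, rtol=1e-4)

    def test_complete_separation_raises(self):
        x = np.array([0.0, 0.0, 1.0, 1.0])
        s = SurvivalSample(ids=np.arange(4), time=np.ones(4),
                           event=np.array([0, 0, 1, 1]), x=x, z=np.empty((4, 0)))
        with pytest.raises(NonConvergenceError):
            fit_logistic_on_delta(s)

    def test_degenerate_outcomes_raise(self):
        s = two_by_two_sample(10, 0, 10, 0)
        with pytest.raises(NonConvergenceError):
            fit_logistic_on_delta(s)


class TestCoxPH:
    def test_two_subject_monotone_likelihood_flagged(self):
        s = SurvivalSample(ids=[0, 1], time=np.array([1.0, 2.0]),
                           event=np.array([1, 1]), x=np.array([1.0, 0.0]),
                           z=np.array([1.0, 0.0]))
        fit = fit_cox_ph(s)
        assert fit.diverged

    def test_constant_covariate_is_zero_with_warning(self):
        s = SurvivalSample(ids=np.arange(4), time=np.array([1.0, 2.0, 3.0, 4.0]),
                           event=np.array([1, 1, 0, 1]), x=np.ones(4), z=np.ones(4))
        with pytest.warns(UserWarning, match="no contrast"):
            fit = fit_cox_ph(s)
        assert fit.coef[0] == 0.0

    def test_toy_data_matches_grid_search(self, toy_sample):
        fit = fit_cox_ph(toy_sample)
        t, d, x = toy_sample.time, toy_sample.event, toy_sample.z[:, 0]

        def pll(g):
            val = 0.0
            for i in np.flatnonzero(d == 1):
                risk = t >= t[i]
                val += g * x[i] - np.log(np.sum(np.exp(g * x[risk])))
            return val

        grid = np.arange(-5, 5, 1e-4)
        best = grid[np.argmax([pll(g) for g in grid])]
        assert fit.coef[0] == pytest.approx(best, abs=1e-3)

    def test_matches_lifelines(self, design_sample):
        import pandas as pd
        from lifelines import CoxPHFitter

        sample, _ = design_sample
        fit = fit_cox_ph(sample)
        df = pd.DataFrame({"T": sample.time, "E": sample.event, "x": sample.x[:, 0]})
        ref = CoxPHFitter().fit(df, duration_col="T", event_col="E")
        assert fit.coef[0] == pytest.approx(ref.params_.iloc[0], abs=1e-4)
        assert fit.se[0] == pytest.approx(ref.standard_errors_.iloc[0], rel=1e-3)

    def test_invariant_to_monotone_time_transform(self, design_sample):
        sample, _ = design_sample
        fit1 = fit_cox_ph(sample)
        warped = SurvivalSample(ids=sample.ids, time=sample.time ** 2,
                                event=sample.event, x=sample.x, z=sample.z,
                                x_names=sample.x_names, z_names=sample.z_names)
        fit2 = fit_cox_ph(warped)
        assert fit1.coef[0] == pytest.approx(fit2.coef[0], abs=1e-8)

    def test_recovers_hazard_ratio_without_cure_fraction(self):
        # pi = 1 for everyone and a PH exposure effect on latency
        cfg = SimulationConfig(n=4000, beta0=30.0, gamma_latency=0.7, seed=17)
        s, _ = generate_cure_sample(cfg)
        fit = fit_cox_ph(s)
        assert fit.coef[0] == pytest.approx(0.7, abs=3 * fit.se[0])

    def test_estimates_flat_across_latency_rates_on_cure_data(self):
        # varying the latency hazard leaves the Cox estimate unchanged
        fits = []
        for rate in (1 / 16, 1 / 8, 1 / 4):
            s, _ = generate_cure_sample(
                SimulationConfig(n=4000, latency_rate=rate, seed=77))
            fits.append(fit_cox_ph(s))
        for i in range(len(fits)):
            for j in range(i + 1, len(fits)):
                combined = np.hypot(fits[i].se[0], fits[j].se[0])
                assert abs(fits[i].coef[0] - fits[j].coef[0]) < 3 * combined

    def test_no_events_raises(self):
        s = SurvivalSample(ids=np.arange(3), time=np.ones(3),
                           event=np.zeros(3), x=np.array([0.0, 1.0, 0.0]),
                           z=np.array([0.0, 1.0, 0.0]))
        with pytest.raises(NonConvergenceError):
            fit_cox_ph(s)


class TestBreslowBaseline:
    def test_nelson_aalen_when_no_covariate_effect(self, toy_sample):
        # gamma = 0: increments are d_k / (# at risk)
        times, inc = breslow_baseline(toy_sample.time, toy_sample.event,
                                      toy_sample.z, np.zeros(1))
        at_risk = [(toy_sample.time >= t).sum() for t in times]
        np.testing.assert_allclose(inc, 1.0 / np.asarray(at_risk))

    def test_ties_share_one_increment(self):
        time = np.array([1.0, 1.0, 2.0, 3.0])
        event = np.array([1, 1, 0, 1])
        times, inc = breslow_baseline(time, event, np.empty((4, 0)), np.empty(0))
        np.testing.assert_array_equal(times, [1.0, 3.0])
        np.testing.assert_allclose(inc, [2 / 4, 1 / 1])
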