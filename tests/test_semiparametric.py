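import numpy as np
import pytest

from curemix import (
    EMState,
    SimulationConfig,
    StepBaseline,
    SurvivalSample,
    bootstrap_se,
    fit_cox_ph,
    fit_em_cure,
    fit_gamma_cure,
    fit_logistic_on_delta,
    generate_cure_sample,
    logistic,
    posterior_susceptible,
)
from curemix.semiparametric import e_step_weights, m_step


def make_state(beta, gamma, times, increments, n):
    return EMState(beta=np.atleast_1d(np.asarray(beta, float)),
                   gamma=np.asarray(gamma, float),
                   baseline=StepBaseline(np.asarray(times, float),
                                         np.asarray(increments, float)),
                   weights=np.ones(n))


class TestEStep:
    def test_weight_formula_cases(self):
        # censored at t=0 (S=1) with pi=0.5 -> w=0.5; event -> w=1;
        # censored beyond the last event time (S=0) -> w=0
        s = SurvivalSample(ids=np.arange(3), time=[0.0, 2.0, 9.0],
                           event=[0, 1, 0], x=np.empty((3, 0)), z=np.empty((3, 0)))
        state = make_state([0.0], [], [2.0], [0.3], 3)
        X = np.ones((3, 1))
        w = e_step_weights(state, s, X, np.empty((3, 0)))
        np.testing.assert_allclose(w, [0.5, 1.0, 0.0], atol=1e-12)

    def test_interior_weight_value(self):
        s = SurvivalSample(ids=[0], time=[1.0], event=[0], x=np.empty((1, 0)),
                           z=np.empty((1, 0)))
        state = make_state([1.2], [], [1.0, 3.0], [0.2, 0.1], 1)
        pi = logistic(1.2)
        surv = 0.8  # product-limit: 1 - 0.2 at t=1
        expect = pi * surv / (1 - pi + pi * surv)
        w = e_step_weights(state, s, np.ones((1, 1)), np.empty((1, 0)))
        assert w[0] == pytest.approx(expect, abs=1e-12)


class TestMStep:
    def test_all_weights_one_reduces_to_cox(self, fast_sample):
        from curemix.naive import weighted_cox_newton

        sample, _ = fast_sample
        gamma, _, _, _, _, _ = weighted_cox_newton(
            sample.time, sample.event, sample.x, weights=np.ones(sample.n))
        ref = fit_cox_ph(sample)
        assert gamma[0] == pytest.approx(ref.coef[0], abs=1e-8)

    def test_baseline_is_km_transform_when_unweighted(self, fast_sample):
        from lifelines import KaplanMeierFitter

        from curemix.naive import breslow_baseline

        sample, _ = fast_sample
        times, inc = breslow_baseline(sample.time, sample.event,
                                      np.empty((sample.n, 0)), np.empty(0),
                                      weights=np.ones(sample.n))
        baseline = StepBaseline(times, inc)
        km = KaplanMeierFitter().fit(sample.time, sample.event)
        grid = np.quantile(sample.time[sample.event == 1], [0.1, 0.3, 0.5, 0.7, 0.9])
        ours = baseline.survival(grid)
        ref = km.predict(grid).to_numpy()
        np.testing.assert_allclose(ours, ref, atol=1e-10)

    def test_single_step_from_truth_weights_increases_loglik(self, fast_sample):
        from curemix.semiparametric import _designs, _observed_loglik

        sample, latent = fast_sample
        X, Z = _designs(sample, True, False)
        w_true = np.where(sample.event == 1, 1.0, latent["Y"].to_numpy().astype(float))
        beta, gamma, baseline = m_step(sample, w_true, X, Z)
        state1 = EMState(beta=np.zeros(X.shape[1]), gamma=gamma, baseline=baseline,
                         weights=w_true)
        state2 = EMState(beta=beta, gamma=gamma, baseline=baseline, weights=w_true)
        assert (_observed_loglik(state2, sample, X, Z)
                > _observed_loglik(state1, sample, X, Z))


class TestFitEMCure:
    def test_loglik_trace_nondecreasing(self, design_sample):
        sample, _ = design_sample
        fit = fit_em_cure(sample)
        trace = np.asarray(fit.diagnostics["loglik_trace"])
        assert np.all(np.diff(trace) >= -1e-6)

    def test_zero_tail_reduces_to_logistic_when_censoring_is_late(self):
        # every censored time beyond the largest event time -> w=0 for all
        # censored -> incidence part is logistic regression on delta
        rng = np.random.default_rng(3)
        n = 300
        x = rng.integers(0, 2, n).astype(float)
        event = rng.random(n) < 0.4
        time = np.where(event, rng.uniform(1, 5, n), rng.uniform(6, 9, n))
        s = SurvivalSample(ids=np.arange(n), time=time, event=event.astype(int),
                           x=x, z=np.empty((n, 0)), x_names=["exposure"])
        fit = fit_em_cure(s)
        ref = fit_logistic_on_delta(s)
        np.testing.assert_allclose(
            fit.estimates[["incidence:intercept", "incidence:exposure"]].to_numpy(),
            ref.coef, atol=1e-6)

    def test_tolerance_tightening_is_stable(self, fast_sample):
        sample, _ = fast_sample
        f1 = fit_em_cure(sample, tol=1e-6)
        f2 = fit_em_cure(sample, tol=1e-7)
        assert np.max(np.abs(f1.estimates.to_numpy() - f2.estimates.to_numpy())) < 1e-4

    def test_agrees_with_parametric_fit_on_gamma_truth(self):
        diffs = []
        for sd in range(8):
            cfg = SimulationConfig(n=2500, latency_family="gamma", latency_shape=2.0,
                                   latency_rate=0.5, seed=400 + sd)
            s, _ = generate_cure_sample(cfg)
            em = float(fit_em_cure(s).estimates["incidence:exposure"])
            gm = float(fit_gamma_cure(s).estimates["incidence:exposure"])
            diffs.append(em - gm)
        diffs = np.asarray(diffs)
        mcse = diffs.std(ddof=1) / np.sqrt(diffs.size)
        assert abs(diffs.mean()) < 3 * max(mcse, 0.02)

    def test_incidence_spread_grows_with_intercept(self):
        # as beta0 grows, pi approaches 1 and the incidence part becomes
        # weakly identified: replicate spread of the EM estimate increases
        def spread(beta0):
            est = []
            for sd in range(10):
                s, _ = generate_cure_sample(
                    SimulationConfig(n=1500, beta0=beta0, seed=600 + sd))
                est.append(float(fit_em_cure(s).estimates["incidence:exposure"]))
            return np.std(est, ddof=1)

        assert spread(2.0) > spread(0.0)


class TestBootstrap:
    def test_reproducible_and_positive(self, fast_sample):
        sample, _ = fast_sample
        sub = sample.subset(np.arange(400))
        se1 = bootstrap_se(sub, B=30, seed=5, latency=False)
        se2 = bootstrap_se(sub, B=30, seed=5, latency=False)
        np.testing.assert_array_equal(se1.to_numpy(), se2.to_numpy())
        assert np.all(se1.to_numpy() > 0)

    def test_stabilizes_with_more_replicates(self, fast_sample):
        sample, _ = fast_sample
        sub = sample.subset(np.arange(400))
        a = bootstrap_se(sub, B=50, seed=1, latency=False)["incidence:exposure"]
        b = bootstrap_se(sub, B=100, seed=2, latency=False)["incidence:exposure"]
        assert abs(a - b) / b < 0.35

    def test_b_must_be_at_least_two(self, fast_sample):
        from curemix import ValidationError

        sample, _ = fast_sample
        with pytest.raises(ValidationError):
            bootstrap_se(sample, B=1)


class TestPosteriorSusceptible:
    def test_limits_and_monotonicity(self, fast_sample):
        sample, _ = fast_sample
        fit = fit_em_cure(sample, latency=False)
        beta = fit.estimates[["incidence:intercept", "incidence:exposure"]].to_numpy()
        p0 = posterior_susceptible(fit, 0.0, x=[1.0])
        assert p0[0] == pytest.approx(logistic(beta[0] + beta[1]), abs=1e-10)
        tmax = fit.extra["baseline"].times[-1]
        assert posterior_susceptible(fit, tmax + 1.0, x=[1.0])[0] == 0.0
        grid = np.linspace(0, tmax + 2, 80)
        vals = posterior_susceptible(fit, grid, x=[1.0])
        assert np.all(np.diff(vals) <= 1e-10)
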