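import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

import siascore as s
from siascore.survival import (bootstrap_auc, cox_fit, km_logrank,
                               logrank_two_sample, lrt_compare, mann_whitney,
                               optimal_cutoff_dichotomize, responder_tests,
                               time_dependent_auc, wald_contributions)


def _two_group_frame(rng, n, hr=1.0, censor_scale=200.0):
    grp = rng.choice(["a", "b"], n)
    rate = np.where(grp == "b", hr / 100.0, 1 / 100.0)
    t = rng.exponential(1 / rate)
    c = rng.exponential(censor_scale, n)
    return pd.DataFrame({"os_time": np.minimum(t, c), "os_event": t <= c,
                         "grp": grp})


class TestKMLogrank:
    def test_identical_groups_p_one(self):
        base = pd.DataFrame({"os_time": [1.0, 2, 3, 4, 5],
                             "os_event": [1, 1, 0, 1, 0]})
        df = pd.concat([base.assign(grp="a"), base.assign(grp="b")],
                       ignore_index=True)
        _, p = km_logrank(df, "grp")
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_hand_product_limit(self):
        df = pd.DataFrame({"os_time": [1.0, 2.0, 3.0],
                           "os_event": [1, 1, 0], "grp": ["a"] * 3})
        df2 = pd.concat([df, df.assign(grp="b")], ignore_index=True)
        curves, _ = km_logrank(df2, "grp")
        sf = curves["a"].survival_function_at_times([1.0, 2.0, 3.0]).to_numpy()
        np.testing.assert_allclose(sf, [2 / 3, 1 / 3, 1 / 3])

    def test_single_group_rejected(self):
        df = pd.DataFrame({"os_time": [1.0, 2.0], "os_event": [1, 1],
                           "grp": ["a", "a"]})
        with pytest.raises(ValueError):
            km_logrank(df, "grp")

    def test_fast_two_group_statistic_matches_lifelines(self):
        from lifelines.statistics import logrank_test
        rng = np.random.default_rng(3)
        df = _two_group_frame(rng, 120, hr=0.6)
        chi2, p = logrank_two_sample(df["os_time"], df["os_event"],
                                     df["grp"] == "b")
        ref = logrank_test(df.loc[df.grp == "a", "os_time"],
                           df.loc[df.grp == "b", "os_time"],
                           df.loc[df.grp == "a", "os_event"],
                           df.loc[df.grp == "b", "os_event"])
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)


def _partial_loglik(beta, x, time, event):
    """Breslow partial log-likelihood for an untied, right-censored sample
    (independent oracle for the Cox fit)."""
    eta = x @ beta
    order = np.argsort(time)
    eta, event = eta[order], np.asarray(event)[order]
    # risk set of subject i: all with time >= t_i
    rev_cumlse = np.logaddexp.accumulate(eta[::-1])[::-1]
    return float(np.sum(eta[event] - rev_cumlse[event]))


class TestCox:
    def test_null_hr_near_one(self):
        rng = np.random.default_rng(4)
        df = _two_group_frame(rng, 4000, hr=1.0)
        fit = cox_fit(df, ["grp"])
        assert fit.summary["HR"].iloc[0] == pytest.approx(1.0, abs=0.08)

    def test_matches_independent_partial_likelihood_oracle(self):
        rng = np.random.default_rng(5)
        n = 60
        x = rng.normal(size=(n, 2))
        t = rng.exponential(np.exp(-(0.5 * x[:, 0] - 0.3 * x[:, 1])))
        event = rng.random(n) > 0.25
        df = pd.DataFrame({"os_time": t, "os_event": event,
                           "x1": x[:, 0], "x2": x[:, 1]})
        fit = cox_fit(df, ["x1", "x2"])
        res = minimize(lambda b: -_partial_loglik(b, x, t, event),
                       np.zeros(2), method="BFGS", tol=1e-12)
        np.testing.assert_allclose(fit.summary["coef"].to_numpy(), res.x,
                                   atol=1e-6)

    def test_time_rescaling_invariance(self):
        rng = np.random.default_rng(6)
        df = _two_group_frame(rng, 300, hr=0.5)
        fit1 = cox_fit(df, ["grp"])
        df2 = df.assign(os_time=df["os_time"] * 7.0)
        fit2 = cox_fit(df2, ["grp"])
        assert fit1.summary["HR"].iloc[0] == pytest.approx(
            fit2.summary["HR"].iloc[0], rel=1e-6)

    def test_no_events_rejected(self):
        df = pd.DataFrame({"os_time": [1.0, 2.0], "os_event": [0, 0],
                           "grp": ["a", "b"]})
        with pytest.raises(ValueError):
            cox_fit(df, ["grp"])


class TestLRT:
    def test_equal_models_lambda_zero(self):
        rng = np.random.default_rng(7)
        df = _two_group_frame(rng, 200, hr=0.7)
        fit = cox_fit(df, ["grp"])
        lam, p = lrt_compare(fit, fit)
        assert lam == 0.0 and p == 1.0

    def test_statistic_consistent_with_stored_loglikelihoods(self):
        rng = np.random.default_rng(8)
        df = _two_group_frame(rng, 200, hr=0.7)
        df["x"] = rng.normal(size=len(df))
        nested = cox_fit(df, ["grp"])
        full = cox_fit(df, ["grp", "x"])
        lam, _ = lrt_compare(nested, full)
        assert lam == pytest.approx(
            2 * (full.log_likelihood - nested.log_likelihood), abs=1e-12)

    def test_non_nested_rejected(self):
        rng = np.random.default_rng(9)
        df = _two_group_frame(rng, 100, hr=1.0)
        df["x"] = rng.normal(size=len(df))
        with pytest.raises(ValueError, match="nested"):
            lrt_compare(cox_fit(df, ["x"]), cox_fit(df, ["grp"]))


class TestBootstrapAUC:
    def test_perfect_score_all_ones(self):
        outcome = np.array([0] * 20 + [1] * 20, dtype=bool)
        score = np.arange(40.0)
        res = bootstrap_auc(outcome, score, n_boot=50, seed=0)
        assert res["aucs"].min() == 1.0

    def test_random_score_centred_at_half(self):
        rng = np.random.default_rng(10)
        outcome = rng.random(2000) < 0.4
        score = rng.normal(size=2000)
        res = bootstrap_auc(outcome, score, n_boot=200, seed=1)
        assert res["median"] == pytest.approx(0.5, abs=0.03)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(11)
        outcome = rng.random(100) < 0.5
        score = rng.normal(size=100)
        a = bootstrap_auc(outcome, score, n_boot=100, seed=42)
        b = bootstrap_auc(outcome, score, n_boot=100, seed=42)
        np.testing.assert_array_equal(a["aucs"], b["aucs"])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_auc(np.ones(10, bool), np.arange(10.0), n_boot=10)


class TestTimeDependentAUC:
    def test_oracle_score_perfect_discrimination(self):
        rng = np.random.default_rng(12)
        t = rng.exponential(50, 100)
        df = pd.DataFrame({"os_time": t, "os_event": np.ones(100, bool)})
        # higher risk score = shorter survival, exactly
        tauc = time_dependent_auc(df, -t, np.quantile(t, [0.3, 0.6]))
        np.testing.assert_allclose(tauc.to_numpy(), 1.0)

    def test_uncensored_matches_pair_count_oracle(self):
        rng = np.random.default_rng(13)
        n = 200
        t = rng.exponential(50, n)
        score = rng.normal(size=n)
        df = pd.DataFrame({"os_time": t, "os_event": np.ones(n, bool)})
        times = np.quantile(t, [0.2, 0.5, 0.8])
        tauc = time_dependent_auc(df, score, times)
        for tt in times:
            case, ctrl = t <= tt, t > tt
            oracle = (score[case][:, None] > score[ctrl][None, :]).mean()
            assert abs(tauc[tt] - oracle) <= 1e-9

    def test_censored_agrees_with_reference_implementation(self):
        sksurv_metrics = pytest.importorskip("sksurv.metrics")
        rng = np.random.default_rng(14)
        n = 300
        t = rng.exponential(100, n)
        c = rng.exponential(150, n)
        obs, ev = np.minimum(t, c), t <= c
        score = -np.log(t) + rng.normal(0, 0.5, n)
        df = pd.DataFrame({"os_time": obs, "os_event": ev})
        times = np.quantile(obs, [0.25, 0.5, 0.75])
        mine = time_dependent_auc(df, score, times).to_numpy()
        y = np.array(list(zip(ev, obs)), dtype=[("e", bool), ("t", float)])
        ref, _ = sksurv_metrics.cumulative_dynamic_auc(y, y, score, times)
        np.testing.assert_allclose(mine, ref, atol=1e-6)

    def test_horizon_beyond_followup_dropped(self):
        df = pd.DataFrame({"os_time": [1.0, 2.0, 3.0],
                           "os_event": [True, True, True]})
        with pytest.warns(UserWarning, match="dropped"):
            tauc = time_dependent_auc(df, [3.0, 2.0, 1.0], [2.5, 99.0])
        assert list(tauc.index) == [2.5]


class TestWaldContributions:
    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(15)
        n = 500
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        t = rng.exponential(np.exp(-(0.8 * x1 + 0.2 * x2)))
        df = pd.DataFrame({"os_time": t, "os_event": np.ones(n, bool),
                           "x1": x1, "x2": x2})
        fit = cox_fit(df, ["x1", "x2"])
        props = wald_contributions(fit)
        assert props.sum() == pytest.approx(1.0, abs=1e-9)
        assert props["x1"] > props["x2"]

    def test_symmetric_predictors_split_evenly(self):
        rng = np.random.default_rng(16)
        n = 4000
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        t = rng.exponential(np.exp(-0.5 * (x1 + x2)))
        df = pd.DataFrame({"os_time": t, "os_event": np.ones(n, bool),
                           "x1": x1, "x2": x2})
        props = wald_contributions(cox_fit(df, ["x1", "x2"]))
        assert props["x1"] == pytest.approx(0.5, abs=0.1)

    def test_single_term_rejected(self):
        rng = np.random.default_rng(17)
        df = _two_group_frame(rng, 100, hr=0.5)
        with pytest.raises(ValueError):
            wald_contributions(cox_fit(df, ["grp"]))


class TestOptimalCutoff:
    def test_degenerate_window_returns_median(self):
        rng = np.random.default_rng(18)
        n = 101
        values = pd.Series(rng.normal(size=n))
        df = pd.DataFrame({"os_time": rng.exponential(10, n),
                           "os_event": np.ones(n, bool)})
        res = optimal_cutoff_dichotomize(values, df, window=(0.5, 0.5))
        assert res["cutoff"] == float(np.median(values))

    def test_recovers_true_step_cutoff(self):
        rng = np.random.default_rng(19)
        n = 400
        values = pd.Series(rng.uniform(0, 1, n))
        rate = np.where(values > 0.5, 0.005, 0.02)
        t = rng.exponential(1 / rate)
        df = pd.DataFrame({"os_time": t, "os_event": np.ones(n, bool)})
        res = optimal_cutoff_dichotomize(values, df)
        assert abs((values <= res["cutoff"]).mean() - 0.5) < 0.10

    def test_identical_values_rejected(self):
        df = pd.DataFrame({"os_time": [1.0] * 12, "os_event": [True] * 12})
        with pytest.raises(ValueError):
            optimal_cutoff_dichotomize(pd.Series([1.0] * 12), df)

    def test_null_scan_is_optimistic(self):
        """Minimising p over cut-offs inflates the rejection rate far above
        the nominal 5% even when the score is unrelated to survival."""
        rng = np.random.default_rng(20)
        hits = 0
        reps = 120
        for _ in range(reps):
            n = 60
            values = pd.Series(rng.normal(size=n))
            df = pd.DataFrame({"os_time": rng.exponential(10, n),
                               "os_event": np.ones(n, bool)})
            res = optimal_cutoff_dichotomize(values, df)
            hits += res["logrank_p"] < 0.05
        assert hits / reps > 0.15


class TestResponderStats:
    def test_exact_u_and_p_for_separated_groups(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6], alternative="less")
        assert u == 0.0
        assert p == pytest.approx(0.05)

    def test_identical_groups_auc_half(self):
        scores = pd.Series([1.0, 2, 3, 1, 2, 3])
        resp = pd.Series(["responder"] * 3 + ["non-responder"] * 3)
        res = responder_tests(scores, resp, n_boot=50)
        assert res["roc_auc"] == 0.5

    def test_perfect_ordering_spearman_one(self):
        scores = pd.Series([1.0, 1, 2, 2, 3, 3])
        resp = pd.Series(["NR", "NR", "PR", "PR", "CR", "CR"])
        res = responder_tests(scores, resp, responder_label="CR",
                              response_order=["NR", "PR", "CR"], n_boot=50)
        assert res["spearman_rho"] == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            responder_tests(pd.Series([1.0, 2.0]),
                            pd.Series(["responder", "responder"]))
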