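"""IPTW machinery and the effect metrics, against hand-built tables,
known simulations and lifelines."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from lifelines.statistics import logrank_test

from survrec.causal import (evaluate_recommender, fit_propensity, ipcw_brier,
                            km_risk_difference, logrank, rmst_difference,
                            smd, weighted_cox_hr)


class TestPropensity:
    def test_coin_flip_groups_give_unit_weights(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (3000, 4))
        g = (rng.random(3000) < 0.5).astype(int)
        wv = fit_propensity(X, g)
        assert abs(wv.weights.mean() - 1.0) < 0.02
        assert wv.weights.std() < 0.1

    def test_stabilized_weight_arithmetic(self):
        # a group-1 patient with e(x) = 0.8 and marginal 0.5 gets the
        # stabilized weight 0.5 / 0.8 = 0.625
        rng = np.random.default_rng(1)
        n = 20_000
        x = rng.normal(0, 1, n)
        p = 1 / (1 + np.exp(-1.5 * x))
        g = (rng.random(n) < p).astype(int)
        wv = fit_propensity(x[:, None], g, truncate=(0, 100))
        marginal = g.mean()
        k = np.where((np.abs(wv.propensity - 0.8) < 0.01) & (g == 1))[0][0]
        np.testing.assert_allclose(wv.weights[k],
                                   marginal / wv.propensity[k], rtol=1e-10)
        assert abs(wv.weights[k] - 0.5 / 0.8) < 0.05

    def test_pseudo_population_sizes(self):
        rng = np.random.default_rng(2)
        n = 5000
        x = rng.normal(0, 1, n)
        p = 1 / (1 + np.exp(-x))
        g = (rng.random(n) < p).astype(int)
        wv = fit_propensity(x[:, None], g)
        # stabilized weights sum to ~n overall and ~marginal share per group
        assert abs(wv.weights.sum() - n) / n < 0.05

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            fit_propensity(np.zeros((10, 1)), np.ones(10))


class TestSmd:
    def test_identical_distributions_zero(self):
        x = np.r_[np.arange(50.0), np.arange(50.0)]
        g = np.r_[np.zeros(50), np.ones(50)]
        assert smd(x, g) == 0.0

    def test_unit_difference_unit_sd(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(1, 1, 20_000), rng.normal(0, 1, 20_000)
        got = smd(np.r_[a, b], np.r_[np.ones(20_000), np.zeros(20_000)])
        assert abs(got - 1.0) < 0.05

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.floats(0.1, 10.0))
    def test_weight_scale_invariance(self, c):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 100)
        g = np.r_[np.zeros(50), np.ones(50)]
        w = rng.uniform(0.5, 2, 100)
        assert abs(smd(x, g, w) - smd(x, g, c * w)) < 1e-12

    def test_zero_variance(self):
        g = np.r_[np.zeros(5), np.ones(5)]
        assert smd(np.full(10, 3.3), g) == 0.0
        with pytest.raises(ValueError):
            smd(np.r_[np.zeros(5), np.full(5, 2.0)] + 5, g)


class TestCoxHr:
    def test_known_rate_ratio(self):
        rng = np.random.default_rng(5)
        n = 4000
        g = np.r_[np.zeros(n // 2), np.ones(n // 2)].astype(int)
        lam = np.where(g == 1, 0.01, 0.02)
        t = rng.exponential(1 / lam)
        hr, lo, hi = weighted_cox_hr(t, np.ones(n, int), g)
        assert 0.42 < hr < 0.58
        assert lo < hr < hi

    def test_uniform_weights_equal_unweighted(self):
        rng = np.random.default_rng(6)
        n = 500
        g = (rng.random(n) < 0.5).astype(int)
        t = rng.exponential(20 + 10 * g)
        hr_u, *_ = weighted_cox_hr(t, np.ones(n, int), g)
        hr_w, *_ = weighted_cox_hr(t, np.ones(n, int), g,
                                   weights=np.ones(n))
        assert abs(np.log(hr_u) - np.log(hr_w)) < 1e-8

    def test_null_permutation_coverage(self):
        rng = np.random.default_rng(7)
        n = 300
        t = rng.exponential(30, n)
        e = np.ones(n, int)
        covered = 0
        reps = 50
        for _ in range(reps):
            g = rng.permutation(np.r_[np.zeros(n // 2),
                                      np.ones(n // 2)]).astype(int)
            _, lo, hi = weighted_cox_hr(t, e, g)
            covered += lo <= 1.0 <= hi
        assert covered / reps >= 0.9


class TestKmMetrics:
    def test_risk_difference_hand_value(self):
        # no censoring: events by tau are 2/4 in group 0 vs 1/4 in group 1
        t = np.array([10, 20, 130, 130, 30, 130, 130, 130.0])
        e = np.array([1, 1, 0, 0, 1, 0, 0, 0])
        g = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        rd, *_ = km_risk_difference(t, e, g, tau=120)
        assert abs(rd - 25.0) < 1e-9

    def test_identical_groups_zero_and_sign_flip(self):
        t = np.array([10, 50, 10, 50.0])
        e = np.array([1, 0, 1, 0])
        g = np.array([0, 0, 1, 1])
        assert abs(km_risk_difference(t, e, g, tau=120)[0]) < 1e-12
        t2 = np.array([10, 130, 30, 130.0])
        e2 = np.array([1, 0, 1, 0])
        g2 = np.array([0, 0, 1, 1])
        a = km_risk_difference(t2, e2, g2, tau=120)[0]
        b = km_risk_difference(t2, e2, 1 - g2, tau=120)[0]
        assert abs(a + b) < 1e-9

    def test_rmst_hand_value(self):
        from survrec.causal import _km_rmst
        got = _km_rmst(np.array([50.0, 150.0]), np.array([1, 1]),
                       np.ones(2), 120.0)
        assert abs(got - 85.0) < 1e-9

    def test_all_survive_difference_zero(self):
        t = np.full(8, 130.0)
        e = np.zeros(8, int)
        g = np.r_[np.zeros(4), np.ones(4)]
        d, *_ = rmst_difference(t, e, g, tau=120)
        assert d == 0.0

    def test_rd_and_drmst_concordant_for_ordered_groups(self):
        rng = np.random.default_rng(8)
        n = 2000
        g = np.r_[np.zeros(n // 2), np.ones(n // 2)].astype(int)
        lam = np.where(g == 1, 0.004, 0.009)   # group 1 stochastically better
        t = rng.exponential(1 / lam)
        rd, *_ = km_risk_difference(t, np.ones(n, int), g, tau=120)
        dr, *_ = rmst_difference(t, np.ones(n, int), g, tau=120)
        assert rd > 0 and dr > 0


class TestBrier:
    def test_perfect_oracle_zero(self):
        t = np.array([10.0, 40.0, 80.0])
        e = np.ones(3, int)
        grid = np.arange(0.0, 121.0)
        S = (grid[None, :] < t[:, None]).astype(float)
        assert ipcw_brier(t, e, S, grid, 120.0) < 1e-12

    def test_constant_half_is_quarter(self):
        rng = np.random.default_rng(9)
        t = rng.exponential(60, 500)
        e = np.ones(500, int)
        grid = np.arange(0.0, 121.0)
        S = np.full((500, len(grid)), 0.5)
        assert abs(ipcw_brier(t, e, S, grid, 120.0) - 0.25) < 1e-12

    def test_matches_scikit_survival_under_censoring(self):
        """Independent cross-check of the IPCW Brier integral against
        scikit-survival on censored data."""
        from sksurv.metrics import integrated_brier_score
        rng = np.random.default_rng(12)
        n = 400
        t_event = rng.exponential(60, n)
        censor = rng.exponential(150, n)
        t = np.minimum(t_event, censor)
        e = (t_event <= censor).astype(int)
        grid = np.linspace(5.0, np.quantile(t, 0.8), 40)
        S = np.exp(-np.outer(rng.uniform(0.005, 0.02, n), grid))
        y = np.array([(bool(ev), ti) for ev, ti in zip(e, t)],
                     dtype=[("event", "?"), ("time", "<f8")])
        ref = integrated_brier_score(y, y, S, grid)
        ours = ipcw_brier(t, e, S, grid, tau=grid[-1])
        assert abs(ours - ref) < 5e-3

    def test_oracle_beats_swapped_curves(self, small_cohort):
        from survrec.cohort import true_survival
        cohort, truth = small_cohort
        grid = np.arange(0.0, 121.0)
        g0 = truth.frame["true_log_hazard0"].to_numpy()
        g1 = truth.frame["true_log_hazard1"].to_numpy()
        S0, S1 = true_survival((g0, g1, 1.0), grid)
        a = cohort["treatment"].to_numpy()
        t = cohort["time_months"].to_numpy()
        e = cohort["event"].to_numpy()
        m = a == 0
        good = ipcw_brier(t[m], e[m], S0[m], grid, 120.0)
        swapped = ipcw_brier(t[m], e[m], S1[m], grid, 120.0)
        assert good < swapped


class TestLogrank:
    def test_matches_lifelines_unweighted(self):
        rng = np.random.default_rng(10)
        t = rng.exponential(10, 300)
        e = (rng.random(300) < 0.7).astype(int)
        g = (rng.random(300) < 0.5).astype(int)
        stat, p = logrank(t, e, g)
        ref = logrank_test(t[g == 1], t[g == 0], e[g == 1], e[g == 0])
        assert abs(stat - ref.test_statistic) < 1e-8
        assert abs(p - ref.p_value) < 1e-10

    def test_no_events_warns_p_one(self):
        with pytest.warns(UserWarning):
            stat, p = logrank([1.0, 2.0], [0, 0], [0, 1])
        assert p == 1.0

    def test_type_one_error_rate(self):
        rng = np.random.default_rng(11)
        n, reps, alpha = 2000, 200, 0.05
        rejections = 0
        for _ in range(reps):
            t = rng.exponential(50, n)
            e = (rng.random(n) < 0.8).astype(int)
            g = (rng.random(n) < 0.5).astype(int)
            _, p = logrank(t, e, g)
            rejections += p < alpha
        assert 0.03 <= rejections / reps <= 0.07


class TestEvaluateRecommender:
    def test_recommend_everyone_reduces_to_treatment_comparison(self,
                                                                small_cohort):
        """With a recommend-everyone rule the Consis. group *is* the
        treated group, so the unweighted metrics equal the plain
        treated-vs-untreated comparison."""
        cohort, _ = small_cohort
        rep = evaluate_recommender(cohort, np.ones(len(cohort), int),
                                   n_boot=0)
        treated = cohort["treatment"].to_numpy(int)
        assert rep.n_consis == int(treated.sum())
        rd_direct, *_ = km_risk_difference(cohort["time_months"],
                                           cohort["event"], treated, tau=120)
        assert abs(rep.rd[0] - rd_direct) < 1e-12
        dr_direct, *_ = rmst_difference(cohort["time_months"],
                                        cohort["event"], treated, tau=120)
        assert abs(rep.drmst[0] - dr_direct) < 1e-12
        _, p_direct = logrank(cohort["time_months"], cohort["event"],
                              treated)
        assert abs(rep.logrank_p - p_direct) < 1e-12

    def test_degenerate_group_flagged(self, small_cohort):
        cohort, _ = small_cohort
        rec = cohort["treatment"].to_numpy()      # everyone consistent
        rep = evaluate_recommender(cohort, rec, n_boot=0)
        assert rep.degenerate

    def test_row_permutation_invariance(self, small_cohort):
        cohort, truth = small_cohort
        rec = (truth.frame["true_ite_rst"].to_numpy() > 0).astype(int)
        rep1 = evaluate_recommender(cohort, rec, n_boot=0)
        perm = np.random.default_rng(1).permutation(len(cohort))
        rep2 = evaluate_recommender(cohort.iloc[perm], rec[perm], n_boot=0)
        assert abs(rep1.hr[0] - rep2.hr[0]) < 1e-6
        assert abs(rep1.rd[0] - rep2.rd[0]) < 1e-9
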