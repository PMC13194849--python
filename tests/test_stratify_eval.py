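import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from dyntac.errors import InvalidInputError
from dyntac.stratify_eval import (
    MONTH_DAYS,
    calibration_at,
    compare_groups,
    decision_curve,
    km_estimate,
    logrank_test,
    optimal_logrank_cutoff,
    td_auc,
)

from conftest import make_survival


class TestKmEstimate:
    def test_no_censoring_drops_one_over_n(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        km = km_estimate(t, np.ones(4, int))
        np.testing.assert_allclose(
            km.set_index("time")["survival"][[1.0, 2.0, 3.0, 4.0]],
            [0.75, 0.5, 0.25, 0.0],
        )

    def test_all_censored_flat_one(self):
        km = km_estimate([5.0, 9.0, 11.0], [0, 0, 0])
        assert np.all(km["survival"].values == 1.0)

    def test_mixed_dataset_matches_hand_table(self):
        # product-limit by hand:
        # t=2 (event, 6 at risk): S=5/6
        # t=4 (censor): no change
        # t=5 (event, 4 at risk): S=5/6*3/4
        # t=7 (event, 3 at risk): S=5/6*3/4*2/3
        # t=9 (censor), t=12 (event, 1 at risk): S=0
        t = np.array([2.0, 4.0, 5.0, 7.0, 9.0, 12.0])
        e = np.array([1, 0, 1, 1, 0, 1])
        km = km_estimate(t, e).set_index("time")["survival"]
        assert km[2.0] == pytest.approx(5 / 6)
        assert km[5.0] == pytest.approx(5 / 6 * 3 / 4)
        assert km[7.0] == pytest.approx(5 / 6 * 3 / 4 * 2 / 3)
        assert km[12.0] == pytest.approx(0.0)

    def test_nonpositive_times_rejected(self):
        with pytest.raises(InvalidInputError):
            km_estimate([-1.0, 0.0], [1, 1])


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = np.array([3.0, 6.0, 8.0, 12.0])
        e = np.array([1, 0, 1, 1])
        stat, p = logrank_test(t, e, t, e)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_tiny_example_matches_risk_set_oracle(self):
        ta = np.array([1.0, 4.0, 6.0, 10.0])
        ea = np.array([1, 1, 0, 1])
        tb = np.array([2.0, 5.0, 7.0, 12.0])
        eb = np.array([1, 0, 1, 1])
        stat, _ = logrank_test(ta, ea, tb, eb)
        # brute-force observed-minus-expected over the pooled risk sets
        t = np.concatenate([ta, tb])
        e = np.concatenate([ea, eb])
        g = np.repeat([0, 1], 4)
        O = E = V = 0.0
        for u in sorted(t[e == 1]):
            at = t >= u
            n = at.sum()
            n1 = (at & (g == 0)).sum()
            d = ((t == u) & (e == 1)).sum()
            d1 = ((t == u) & (e == 1) & (g == 0)).sum()
            O += d1
            E += d * n1 / n
            if n > 1:
                V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        assert stat == pytest.approx((O - E) ** 2 / V, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(InvalidInputError):
            logrank_test([], [], [1.0], [1])


class TestOptimalCutoff:
    def test_separable_clusters_cut_in_gap(self):
        rng = np.random.default_rng(0)
        n = 40
        # marker independent of survival within each cluster, disjoint across
        marker = np.concatenate([rng.uniform(0, 1, n // 2), rng.uniform(3, 4, n // 2)])
        t = np.concatenate([rng.permutation(np.linspace(1, 20, n // 2)),
                            rng.permutation(np.linspace(101, 120, n // 2))])
        e = np.ones(n, int)
        res = optimal_logrank_cutoff(marker, t, e)
        assert 1.0 < res.cutoff < 3.0
        assert res.low_marker_is_high_risk

    def test_constant_marker_rejected(self):
        with pytest.raises(InvalidInputError):
            optimal_logrank_cutoff(np.ones(10), np.arange(1.0, 11), np.ones(10, int))

    def test_group_size_constraint_respected(self):
        rng = np.random.default_rng(1)
        marker = np.concatenate([[-9.0], rng.normal(size=19)])
        t = rng.exponential(100, 20)
        res = optimal_logrank_cutoff(marker, t, np.ones(20, int), min_group_frac=0.15)
        n_low = res.low_marker.sum()
        assert 3 <= n_low <= 17


class TestTdAuc:
    def test_perfect_marker_auc_one(self):
        n = 60
        t = np.arange(1.0, n + 1)
        e = np.ones(n, int)
        marker = -t  # larger marker fails sooner
        res = td_auc(marker, t, e, horizon=30.5)
        assert res.auc == pytest.approx(1.0)

    def test_uncensored_equals_rank_statistic(self):
        rng = np.random.default_rng(2)
        n = 150
        m = rng.normal(size=n)
        t = rng.exponential(200, n)
        e = np.ones(n, int)
        h = 180.0
        res = td_auc(m, t, e, h)
        cases, ctrl = m[t <= h], m[t > h]
        u = mannwhitneyu(cases, ctrl).statistic
        assert res.auc == pytest.approx(u / (len(cases) * len(ctrl)), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        m, t, e = make_survival(200, rng, beta=1.0)
        h = np.median(t)
        a = td_auc(m, t, e, h).auc
        b = td_auc(np.exp(3 * m) + 7, t, e, h).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_no_cases_raises(self):
        t = np.full(10, 100.0)
        with pytest.raises(InvalidInputError):
            td_auc(np.arange(10.0), t, np.ones(10, int), horizon=50.0)


class TestCalibration:
    def test_constant_prediction_brier_is_p_one_minus_p(self):
        rng = np.random.default_rng(4)
        n = 400
        t = rng.exponential(100, n)
        e = np.ones(n, int)
        h = float(np.median(t))
        prev = float(np.mean(t <= h))
        with pytest.warns(UserWarning):
            res = calibration_at(np.full(n, prev), t, e, h)
        assert res.brier == pytest.approx(prev * (1 - prev), rel=1e-9)
        assert not res.slope_defined

    def test_perfectly_calibrated_slope_near_one(self):
        rng = np.random.default_rng(5)
        n = 3000
        z = rng.standard_normal(n)
        lam = 0.004 * np.exp(0.8 * z)
        t = rng.exponential(1 / lam)
        e = np.ones(n, int)
        h = 250.0
        risk = 1.0 - np.exp(-lam * h)  # true model risks
        res = calibration_at(np.clip(risk, 1e-6, 1 - 1e-6), t, e, h)
        assert res.slope == pytest.approx(1.0, abs=0.1)
        assert res.intercept == pytest.approx(0.0, abs=0.1)

    def test_anticorrelated_predictions_negative_slope(self):
        rng = np.random.default_rng(6)
        n = 500
        z = rng.standard_normal(n)
        lam = 0.004 * np.exp(z)
        t = rng.exponential(1 / lam)
        e = np.ones(n, int)
        h = 250.0
        wrong = 1.0 - np.exp(-0.004 * np.exp(-z) * h)  # inverted risk ordering
        res = calibration_at(np.clip(wrong, 1e-6, 1 - 1e-6), t, e, h)
        assert res.slope < 0

    def test_risks_outside_unit_interval_rejected(self):
        with pytest.raises(InvalidInputError):
            calibration_at([0.2, 1.2], [5.0, 6.0], [1, 1], 4.0)


class TestDecisionCurve:
    def test_treat_none_is_zero(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0.1, 0.9, 50)
        t = rng.exponential(100, 50)
        dca = decision_curve(p, t, np.ones(50, int), 80.0, [0.1, 0.3, 0.5])
        assert np.all(dca["nb_none"].values == 0.0)

    def test_treat_all_limit_is_prevalence(self):
        rng = np.random.default_rng(8)
        n = 200
        t = rng.exponential(100, n)
        e = np.ones(n, int)
        h = 90.0
        prev = float(np.mean(t <= h))
        dca = decision_curve(np.full(n, 0.5), t, e, h, [1e-6 + 0.001])
        assert dca["nb_all"].iloc[0] == pytest.approx(prev, abs=0.01)

    def test_model_coincides_with_treat_all_when_all_positive(self):
        rng = np.random.default_rng(9)
        n = 100
        t = rng.exponential(100, n)
        e = (rng.random(n) < 0.8).astype(int)
        p = rng.uniform(0.6, 0.9, n)
        dca = decision_curve(p, t, e, 90.0, [0.2, 0.4])
        np.testing.assert_allclose(dca["nb_model"], dca["nb_all"], atol=1e-12)

    def test_matches_exhaustive_counting_uncensored(self):
        t = np.array([10.0, 20, 30, 40, 50, 60, 70, 80, 90, 100])
        e = np.ones(10, int)
        p = np.array([0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1, 0.05])
        h = 45.0
        for pt in (0.15, 0.35, 0.55, 0.75):
            pos = p >= pt
            tp = np.sum(pos & (t <= h)) / 10
            fp = np.sum(pos & (t > h)) / 10
            expected = tp - fp * pt / (1 - pt)
            got = decision_curve(p, t, e, h, [pt])["nb_model"].iloc[0]
            assert got == pytest.approx(expected, abs=1e-12)

    def test_empty_threshold_grid_rejected(self):
        with pytest.raises(InvalidInputError):
            decision_curve([0.5, 0.5], [1.0, 2.0], [1, 1], 1.5, [])


class TestCompareGroups:
    def test_balanced_2x2_fisher_p_one(self):
        # 8/9 vs 7/8 split: Fisher two-sided p rounds to 1
        g = np.array([0] * 17 + [1] * 15)
        sex = np.array([0] * 8 + [1] * 9 + [0] * 7 + [1] * 8)
        df = pd.DataFrame({"sex": sex})
        res = compare_groups(df, g, categorical=["sex"])
        assert res.loc["sex", "p"] > 0.999

    def test_identical_continuous_samples_high_p(self):
        x = np.concatenate([np.arange(10.0), np.arange(10.0)])
        g = np.repeat([0, 1], 10)
        res = compare_groups(pd.DataFrame({"v": x}), g)
        assert res.loc["v", "p"] > 0.95

    def test_mwu_matches_exhaustive_permutation(self):
        a = np.array([1.2, 3.4, 0.7, 5.1, 2.2])
        b = np.array([4.4, 6.1, 5.9, 7.2, 3.3])
        g = np.repeat([0, 1], 5)
        df = pd.DataFrame({"v": np.concatenate([a, b])})
        res = compare_groups(df, g)
        # exhaustive permutation distribution of the U statistic
        pooled = np.concatenate([a, b])
        u_obs = mannwhitneyu(a, b, alternative="two-sided").statistic
        count = 0
        total = 0
        for comb in itertools.combinations(range(10), 5):
            xa = pooled[list(comb)]
            xb = pooled[[i for i in range(10) if i not in comb]]
            u = mannwhitneyu(xa, xb, alternative="two-sided").statistic
            d_obs = abs(u_obs - 12.5)
            if abs(u - 12.5) >= d_obs - 1e-9:
                count += 1
            total += 1
        assert res.loc["v", "test"] in ("mann_whitney_u", "t_test")
        if res.loc["v", "test"] == "mann_whitney_u":
            assert res.loc["v", "p"] == pytest.approx(count / total, abs=0.02)

    def test_rxc_fisher_mc_reasonable(self):
        rng = np.random.default_rng(10)
        g = rng.integers(0, 2, 60)
        cat = rng.choice(list("abc"), 60)
        res = compare_groups(pd.DataFrame({"c": cat}), g, categorical=["c"],
                             mc_draws=20000, seed=1)
        assert 0.0 < res.loc["c", "p"] <= 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(InvalidInputError):
            compare_groups(pd.DataFrame({"v": [1.0, 2.0]}), np.array([0, 0]))


def test_marker_across_three_groups_kruskal():
    from dyntac.stratify_eval import compare_marker_across_groups

    rng = np.random.default_rng(12)
    v = rng.normal(size=90)
    g = np.repeat(["a", "b", "c"], 30)
    res = compare_marker_across_groups(v, g)
    assert res["test"] == "kruskal_wallis"
    assert res["n_groups"] == 3
    assert res["p"] > 0.01  # null data


def test_low_marker_high_risk_orientation():
    """Low marker values carrying risk must be flagged as the high-risk group."""
    rng = np.random.default_rng(11)
    n = 80
    marker = rng.normal(size=n)
    lam = 0.01 * np.exp(-1.5 * marker)  # low marker -> high hazard
    t = rng.exponential(1 / lam)
    res = optimal_logrank_cutoff(marker, t, np.ones(n, int))
    assert res.low_marker_is_high_risk
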