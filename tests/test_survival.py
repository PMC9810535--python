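"""Preranked GSEA, thresholding, log-rank/trend, Cox, essentiality."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from hscnet.simulate import CohortSimConfig, gen_cohort
from hscnet.survival import (
    ccle_stratify_essentiality,
    cox_model,
    gsea_es,
    km_logrank,
    marginal_hazard_curve,
    preranked_gsea,
    sample_rank_metric,
    youden_threshold,
)


def _running_sum_oracle(metric, hit, weight):
    """Independent step-by-step running sum, returning the signed extremum."""
    n = len(metric)
    k = hit.sum()
    w = np.abs(metric) ** weight if weight != 0 else np.ones(n)
    denom = w[hit].sum()
    rs, cur, best = [], 0.0, 0.0
    for i in range(n):
        cur += w[i] / denom if hit[i] else -1.0 / (n - k)
        rs.append(cur)
        if abs(cur) > abs(best):
            best = cur
    return best


class TestGseaES:
    def test_top_k_unweighted_matches_oracle(self):
        metric = np.linspace(3, -3, 10)
        hit = np.zeros(10, dtype=bool)
        hit[:3] = True
        es = gsea_es(metric, hit, weight=0)
        assert es == pytest.approx(_running_sum_oracle(metric, hit, 0))
        assert es == pytest.approx(1.0)  # all hits lead the ranking

    @pytest.mark.parametrize("weight", [0, 1])
    def test_random_sets_match_oracle(self, weight):
        rng = np.random.default_rng(4)
        for _ in range(10):
            metric = np.sort(rng.normal(size=10))[::-1]
            hit = np.zeros(10, dtype=bool)
            hit[rng.choice(10, 4, replace=False)] = True
            assert gsea_es(metric, hit, weight) == pytest.approx(
                _running_sum_oracle(metric, hit, weight)
            )

    def test_complement_antisymmetry_unweighted(self):
        rng = np.random.default_rng(5)
        metric = np.sort(rng.normal(size=20))[::-1]
        hit = np.zeros(20, dtype=bool)
        hit[rng.choice(20, 6, replace=False)] = True
        assert gsea_es(metric, ~hit, 0) == pytest.approx(-gsea_es(metric, hit, 0))

    def test_interleaved_set_is_neutral(self):
        metric = pd.Series(np.linspace(2, -2, 20),
                           index=[f"g{i}" for i in range(20)])
        interleaved = [f"g{i}" for i in range(0, 20, 4)]
        res = preranked_gsea(metric, interleaved, weight=0, n_perm=200, seed=0)
        assert abs(res.es) < 0.3
        assert res.call == "neutral"

    def test_empty_intersection_rejected(self):
        metric = pd.Series([1.0, 0.5, -1.0], index=["a", "b", "c"])
        with pytest.raises(ValueError):
            preranked_gsea(metric, ["x", "y", "z"])

    def test_nes_sign_matches_es(self):
        rng = np.random.default_rng(6)
        metric = pd.Series(rng.normal(size=100),
                           index=[f"g{i}" for i in range(100)])
        top = metric.sort_values(ascending=False).index[:10]
        res = preranked_gsea(metric, list(top), n_perm=200, seed=1)
        assert res.es > 0 and res.nes > 0 and res.call == "enriched"


class TestSampleRankMetric:
    def test_sample_equal_to_cohort_mean_gives_zero(self):
        expr = pd.DataFrame([[1.0, 2], [3, 4], [2, 3]],
                            index=["s1", "s2", "s3"], columns=["g1", "g2"])
        metric = sample_rank_metric(expr, "s3")  # s3 equals column means
        assert np.allclose(metric, 0.0)

    def test_hand_three_by_three(self):
        expr = pd.DataFrame([[1.0, 5, 0], [2, 6, 3], [3, 7, 9]],
                            index=["s1", "s2", "s3"],
                            columns=["g1", "g2", "g3"])
        metric = sample_rank_metric(expr, "s1")
        assert np.allclose(metric, [1 - 2, 5 - 6, 0 - 4])

    def test_study_centering_removes_study_offsets(self):
        rng = np.random.default_rng(7)
        expr = pd.DataFrame(rng.normal(size=(20, 5)),
                            index=[f"s{i}" for i in range(20)],
                            columns=[f"g{i}" for i in range(5)])
        study = pd.Series(["X"] * 10 + ["Y"] * 10, index=expr.index)
        before = sample_rank_metric(expr, "s0", study=study)
        shifted = expr.copy()
        shifted.iloc[10:] += 100.0  # batch offset on study Y
        after = sample_rank_metric(shifted, "s0", study=study)
        assert np.allclose(before, after)


class TestYouden:
    def test_perfect_separation(self):
        score = np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9])
        outcome = np.array([0, 0, 0, 1, 1, 1])
        t = youden_threshold(score, outcome)
        assert t == pytest.approx(0.5)
        assert ((score > t) == outcome.astype(bool)).all()

    def test_matches_exhaustive_grid(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            score = rng.normal(size=40)
            outcome = rng.random(40) < 0.4
            if outcome.all() or not outcome.any():
                continue
            t = youden_threshold(score, outcome)

            def j_at(c):
                pred = score > c
                return (pred & outcome).sum() / outcome.sum() + \
                    (~pred & ~outcome).sum() / (~outcome).sum() - 1

            uniq = np.unique(score)
            grid = (uniq[:-1] + uniq[1:]) / 2
            best = grid[np.argmax([j_at(c) for c in grid])]
            assert j_at(t) == pytest.approx(max(j_at(c) for c in grid))
            assert t == pytest.approx(best)

    def test_six_point_hand_enumeration(self):
        score = np.array([1.0, 2, 3, 4, 5, 6])
        outcome = np.array([0, 1, 0, 1, 1, 1])
        # hand confusion tables: J over cuts 1.5..5.5 = .25, 0, .5, .25, -.25
        assert youden_threshold(score, outcome) == pytest.approx(3.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            youden_threshold([1, 2, 3], [1, 1, 1])


def _hand_logrank(time, event, group):
    """Two-group log-rank chi-square from first principles."""
    o_minus_e, var = 0.0, 0.0
    for t in sorted(set(time[event == 1])):
        at = time >= t
        n = at.sum()
        n1 = (at & (group == 1)).sum()
        d = int(((time == t) & (event == 1)).sum())
        d1 = int(((time == t) & (event == 1) & (group == 1)).sum())
        if n < 2:
            continue
        o_minus_e += d1 - d * n1 / n
        var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestKMLogrank:
    def test_identical_groups_no_signal(self):
        time = np.tile([5.0, 10, 15, 20], 2)
        event = np.ones(8, dtype=int)
        groups = np.repeat(["a", "b"], 4)
        res = km_logrank(groups, time, event)
        assert res.logrank_chi2 == pytest.approx(0.0, abs=1e-10)

    def test_eight_subject_example_matches_hand_table(self):
        time = np.array([6.0, 7, 10, 15, 19, 25, 30, 36])
        event = np.array([1, 0, 1, 1, 0, 1, 1, 1])
        group = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        res = km_logrank(group, time, event)
        assert res.logrank_chi2 == pytest.approx(_hand_logrank(time, event, group))

    def test_strong_effect_detected(self):
        rng = np.random.default_rng(9)
        n = 200
        grp = np.repeat([0, 1], n // 2)
        t = rng.exponential(np.where(grp == 1, 100 / 3, 100))
        res = km_logrank(grp, t, np.ones(n, dtype=int))
        assert res.logrank_p < 1e-3

    def test_trend_across_ordered_groups(self):
        rng = np.random.default_rng(10)
        n = 300
        grp = np.repeat([0, 1, 2], n // 3)
        t = rng.exponential(100 / (1.0 + grp))
        res = km_logrank(grp, t, np.ones(n, dtype=int), order=[0, 1, 2])
        assert res.trend_p is not None and res.trend_p < 1e-4
        # reversing the scores must not change the trend chi-square
        res_rev = km_logrank(grp, t, np.ones(n, dtype=int), order=[2, 1, 0])
        assert res.trend_chi2 == pytest.approx(res_rev.trend_chi2)

    def test_truncation_censors_at_cutoff(self):
        time = np.array([10.0, 50, 200, 400])
        event = np.array([1, 1, 1, 1])
        res = km_logrank(["a", "a", "b", "b"], time, event, truncate_days=100)
        curve_b = res.curves["b"]
        assert curve_b.index.max() == 100


def _cox_score_root(time, x):
    """Closed-form score-equation root for a single covariate, no ties,
    all events: solves sum(x_i - weighted risk-set mean) = 0."""
    order = np.argsort(time)
    x = x[order]

    def score(beta):
        s = 0.0
        for i in range(len(x)):
            risk = x[i:]
            w = np.exp(beta * risk)
            s += x[i] - (risk * w).sum() / w.sum()
        return s

    return optimize.brentq(score, -5, 5)


class TestCox:
    def test_six_subject_no_ties_matches_score_equation_root(self):
        time = np.array([3.0, 5, 7, 11, 13, 17])
        x = np.array([0.2, -1.0, 0.5, 1.5, -0.3, 0.9])
        res = cox_model(pd.DataFrame({"x": x}), time, np.ones(6, dtype=int))
        beta_hat = np.log(res.summary.loc["x", "hr"])
        assert beta_hat == pytest.approx(_cox_score_root(time, x), abs=1e-5)

    def test_null_covariate_hr_near_one(self):
        rng = np.random.default_rng(11)
        n = 400
        x = rng.normal(size=n)
        t = rng.exponential(100, size=n)
        res = cox_model(pd.DataFrame({"x": x}), t, np.ones(n, dtype=int))
        fit = res.fits["x"]
        assert fit.ci_low <= 1.0 <= fit.ci_high

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_model(pd.DataFrame({"x": np.ones(10)}),
                      np.arange(1, 11, dtype=float), np.ones(10, dtype=int))

    def test_planted_binary_hr_recovered(self):
        cfg = CohortSimConfig(n_patients=400, true_hr=2.0, seed=3, n_genes=20)
        _, clin, truth = gen_cohort(cfg)
        res = cox_model(pd.DataFrame({"enriched": truth.astype(float)}),
                        clin["time"], clin["event"])
        fit = res.fits["enriched"]
        assert fit.ci_low < 2.0 < fit.ci_high


class TestMarginalHazard:
    def test_null_effect_flat_at_one(self):
        rng = np.random.default_rng(12)
        n = 2000
        df = pd.DataFrame({"x": rng.normal(size=n),
                           "age": rng.uniform(20, 80, n)})
        res = cox_model(df, rng.exponential(100, n), np.ones(n, dtype=int))
        curve = marginal_hazard_curve(res, "x", np.linspace(-1, 1, 9))
        assert np.allclose(curve["hr"], 1.0, atol=0.1)
        assert ((curve["ci_low"] <= 1.0 + 1e-9) | (curve["hr"] == 1.0)).all()

    def test_monotone_for_planted_linear_effect(self):
        rng = np.random.default_rng(13)
        n = 1500
        x = rng.normal(size=n)
        t = rng.exponential(100 * np.exp(-0.7 * x))
        res = cox_model(pd.DataFrame({"x": x}), t, np.ones(n, dtype=int))
        curve = marginal_hazard_curve(res, "x", np.linspace(-1.5, 1.5, 7), ref=0.0)
        assert (np.diff(curve["hr"]) > 0).all()

    def test_band_widens_with_smaller_n(self):
        rng = np.random.default_rng(14)

        def width(n):
            x = rng.normal(size=n)
            t = rng.exponential(100 * np.exp(-0.3 * x))
            res = cox_model(pd.DataFrame({"x": x}), t, np.ones(n, dtype=int))
            c = marginal_hazard_curve(res, "x", np.array([1.5]), ref=0.0)
            return float((c["ci_high"] - c["ci_low"]).iloc[0])

        assert width(100) > width(2000)

    def test_per_age_curves_with_interaction(self):
        rng = np.random.default_rng(15)
        n = 1500
        x = rng.normal(size=n)
        age = rng.uniform(20, 80, n)
        t = rng.exponential(100 * np.exp(-(0.2 + 0.01 * age) * x))
        df = pd.DataFrame({"x": x, "age": age, "x:age": x * age})
        res = cox_model(df, t, np.ones(n, dtype=int))
        curve = marginal_hazard_curve(res, "x", np.array([1.0]), ref=0.0,
                                      age_col="age", ages=[30, 70])
        hr30 = curve.loc[curve.age == 30, "hr"].iloc[0]
        hr70 = curve.loc[curve.age == 70, "hr"].iloc[0]
        assert hr70 > hr30  # steeper exposure effect at older ages


class TestEssentiality:
    def test_boundary_value_is_high_and_hand_arithmetic(self):
        expr = pd.Series({"l1": 0.2, "l2": 1.0, "l3": 2.5, "l4": 0.5})
        ceres = pd.DataFrame(
            {"gA": [-0.1, -0.9, -1.1, -0.2], "gB": [0.0, 0.1, -0.2, 0.3]},
            index=["l1", "l2", "l3", "l4"],
        )
        groups, diff = ccle_stratify_essentiality(expr, ceres)
        assert groups["l2"] == "high"  # cutoff boundary assigned high
        assert diff["gA"] == pytest.approx((-0.9 + -1.1) / 2 - (-0.1 + -0.2) / 2)
        assert diff["gB"] == pytest.approx((0.1 + -0.2) / 2 - (0.0 + 0.3) / 2)

    def test_equal_means_zero(self):
        expr = pd.Series({"l1": 0.0, "l2": 2.0})
        ceres = pd.DataFrame({"g": [-0.5, -0.5]}, index=["l1", "l2"])
        _, diff = ccle_stratify_essentiality(expr, ceres)
        assert diff["g"] == 0.0

    def test_empty_group_rejected(self):
        expr = pd.Series({"l1": 2.0, "l2": 3.0})
        ceres = pd.DataFrame({"g": [0.1, 0.2]}, index=["l1", "l2"])
        with pytest.raises(ValueError):
            ccle_stratify_essentiality(expr, ceres)


class TestEndToEndEnrichmentCall:
    def test_planted_cohort_sensitivity(self):
        cfg = CohortSimConfig(n_patients=120, seed=4, n_genes=400)
        expr, clin, truth = gen_cohort(cfg)
        net = [f"g{i:04d}" for i in range(50)]
        rng = np.random.default_rng(0)
        calls = np.array([
            preranked_gsea(sample_rank_metric(expr, s), net,
                           n_perm=200, seed=rng).call == "enriched"
            for s in expr.index
        ])
        enriched = truth.to_numpy()
        sens = calls[enriched].mean()
        assert sens >= 0.9
        assert calls[~enriched].mean() <= 0.2
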