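"""Diagnostic-accuracy statistics: ROC, operating points, bootstrap,
DeLong, triage, group comparisons."""

import math

import numpy as np
import pytest
from scipy import stats
from hypothesis import given, settings, strategies as st

from ptaupet.evaluate import (
    auc_trapezoid,
    bonferroni,
    bootstrap_ci,
    chi_square,
    cohens_d,
    compare_groups,
    delong_compare,
    fit_logistic,
    operating_metrics,
    power_two_sample,
    roc_curve,
    spearman,
    threshold_at_sensitivity,
    threshold_at_specificity,
    two_threshold_classify,
    youden_point,
)


def random_instance(rng, n=40, ties=True):
    scores = rng.normal(size=n)
    if ties:
        scores = np.round(scores, 1)
    labels = (rng.random(n) < 0.4).astype(int)
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    return scores, labels


class TestRocCurve:
    def test_perfect_separation(self):
        roc = roc_curve([0.0, 0.0, 1.0, 1.0], [0, 0, 1, 1])
        assert roc.auc == pytest.approx(1.0)

    def test_all_ties_give_half(self):
        roc = roc_curve([0.3] * 6, [0, 1, 0, 1, 0, 1])
        assert roc.auc == pytest.approx(0.5)

    def test_two_pair_brute_force(self):
        # pairs: (0.1+, 0.2-) discordant, (0.3+, 0.2-) concordant -> 0.5
        roc = roc_curve([0.1, 0.3, 0.2], [1, 1, 0])
        assert roc.auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            roc_curve([1.0, 2.0], [1, 1])

    def test_trace_monotonicity(self):
        rng = np.random.default_rng(0)
        scores, labels = random_instance(rng, 80)
        roc = roc_curve(scores, labels)
        assert (np.diff(roc.sens) <= 1e-12).all()
        assert (np.diff(roc.spec) >= -1e-12).all()

    def test_rank_auc_equals_trapezoid_and_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        for _ in range(50):
            scores, labels = random_instance(rng)
            roc = roc_curve(scores, labels)
            assert roc.auc == pytest.approx(auc_trapezoid(roc), abs=1e-12)
            assert roc.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        scores, labels = random_instance(rng)
        base = roc_curve(scores, labels).auc
        assert roc_curve(np.exp(scores), labels).auc == pytest.approx(base)
        assert roc_curve(3.0 * scores + 7.0, labels).auc == pytest.approx(base)


def brute_force_best_j(scores, labels):
    best = -np.inf
    thresholds = np.append(np.unique(scores), np.max(scores) + 1)
    for t in thresholds:
        predicted = (scores >= t).astype(int)
        sens = predicted[labels == 1].mean()
        spec = 1 - predicted[labels == 0].mean()
        best = max(best, sens + spec - 1)
    return best


class TestOperatingPoints:
    def test_youden_perfect_separation(self):
        roc = roc_curve([1.0, 2.0, 5.0, 6.0], [0, 0, 1, 1])
        point = youden_point(roc)
        assert point.youden_j == pytest.approx(1.0)
        assert point.sens == point.spec == 1.0

    def test_youden_all_ties(self):
        roc = roc_curve([2.0] * 4, [0, 1, 0, 1])
        assert youden_point(roc).youden_j == pytest.approx(0.0)

    def test_youden_matches_exhaustive_scan(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            scores, labels = random_instance(rng, 30)
            roc = roc_curve(scores, labels)
            assert youden_point(roc).youden_j == pytest.approx(
                brute_force_best_j(scores, labels), abs=1e-12
            )

    def test_youden_tie_break_prefers_sensitivity(self):
        # J is maximised at two thresholds; the lower one keeps sens higher
        scores = np.array([1.0, 2.0, 3.0, 4.0])
        labels = np.array([0, 1, 0, 1])
        point = youden_point(roc_curve(scores, labels))
        assert point.threshold == pytest.approx(2.0)
        assert point.sens == pytest.approx(1.0)

    def test_sensitivity_target_one_takes_all(self):
        scores = np.array([0.2, 0.5, 0.9, 1.4])
        labels = np.array([0, 1, 0, 1])
        point = threshold_at_sensitivity(roc_curve(scores, labels), 1.0)
        assert point.sens == 1.0
        assert point.threshold <= 0.5

    def test_fixed_targets_on_separated_data(self):
        roc = roc_curve([1.0, 2.0, 5.0, 6.0], [0, 0, 1, 1])
        for point in (
            threshold_at_sensitivity(roc, 0.9),
            threshold_at_specificity(roc, 0.9),
        ):
            assert point.sens == 1.0 and point.spec == 1.0
            assert point.threshold == youden_point(roc).threshold

    def test_fixed_sensitivity_brute_force(self):
        scores = np.array([2.0, 3.0, 4.0, 5.0, 1.0, 2.0, 3.0])
        labels = np.array([1, 1, 1, 1, 0, 0, 0])
        roc = roc_curve(scores, labels)
        point = threshold_at_sensitivity(roc, 0.75)
        # exhaustive scan: largest threshold with sens >= 0.75 is 3.0
        assert point.threshold == pytest.approx(3.0)
        assert point.sens == pytest.approx(0.75)
        assert point.spec == pytest.approx(2.0 / 3.0)

    def test_fixed_targets_match_scan_randomized(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            scores, labels = random_instance(rng, 25)
            roc = roc_curve(scores, labels)
            for target in (0.6, 0.8, 0.95):
                point = threshold_at_sensitivity(roc, target)
                assert point.sens >= target - 1e-9
                # no larger candidate threshold still meets the target
                larger = roc.thresholds > point.threshold
                assert (roc.sens[larger] < target - 1e-12).all()

    def test_unattainable_specificity_reports_max(self):
        roc = roc_curve([1.0, 1.0, 1.0, 1.0], [0, 1, 0, 1])
        with pytest.raises(ValueError, match="maximum attainable"):
            threshold_at_specificity(roc, 0.9)


class TestOperatingMetrics:
    def test_perfect_prediction(self):
        m = operating_metrics([0, 0, 1, 1], [0, 0, 1, 1])
        assert (m.sens, m.spec, m.ppv, m.npv, m.accuracy) == (1, 1, 1, 1, 1)

    def test_hand_computed_confusion(self):
        # TP=3 FP=1 TN=4 FN=2
        predicted = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        truth = [1, 1, 1, 0, 1, 1, 0, 0, 0, 0]
        m = operating_metrics(predicted, truth)
        assert m.sens == pytest.approx(0.6)
        assert m.spec == pytest.approx(0.8)
        assert m.ppv == pytest.approx(0.75)
        assert m.npv == pytest.approx(2.0 / 3.0)
        assert m.accuracy == pytest.approx(0.7)

    def test_undefined_ppv_is_missing(self):
        m = operating_metrics([0, 0, 0], [0, 1, 0])
        assert m.ppv is None
        assert m.npv is not None

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            operating_metrics([1, 0], [1])


class TestBootstrap:
    def test_constant_data_degenerate_interval(self):
        lo, hi = bootstrap_ci(np.mean, np.full(30, 5.0), B=200, rng=0)
        assert lo == hi == pytest.approx(5.0)

    def test_ordering_and_determinism(self):
        data = np.random.default_rng(5).normal(size=60)
        a = bootstrap_ci(np.mean, data, B=300, rng=42)
        b = bootstrap_ci(np.mean, data, B=300, rng=42)
        assert a == b
        assert a[0] <= a[1]

    def test_width_matches_normal_theory(self):
        # mean of n=200 standard normals: 95% CI width ~ 2*1.96/sqrt(200)
        rng = np.random.default_rng(6)
        widths = []
        for seed in range(5):
            data = rng.normal(size=200)
            lo, hi = bootstrap_ci(np.mean, data, B=1000, rng=seed)
            widths.append(hi - lo)
        expected = 2 * 1.96 / math.sqrt(200)
        assert float(np.mean(widths)) == pytest.approx(expected, rel=0.2)

    def test_paired_resampling_keeps_rows_aligned(self):
        x = np.arange(50.0)
        y = 2.0 * x
        lo, hi = bootstrap_ci(
            lambda a, b: float(np.corrcoef(a, b)[0, 1]), (x, y), B=200, rng=1
        )
        assert lo == pytest.approx(1.0) and hi == pytest.approx(1.0)

    def test_subsample_scheme_runs(self):
        data = np.random.default_rng(7).normal(size=100)
        lo, hi = bootstrap_ci(np.mean, data, B=200, rng=2, scheme="subsample")
        assert lo <= hi

    def test_failing_statistic_errors(self):
        def bad(_):
            raise RuntimeError("nope")

        with pytest.raises(RuntimeError, match="replicates"):
            bootstrap_ci(bad, np.arange(10.0), B=100, rng=0)


class TestSpearman:
    def test_monotone_relationships(self):
        x = np.arange(10.0)
        assert spearman(x, x ** 3, ci=False).r == pytest.approx(1.0)
        assert spearman(x, -x, ci=False).r == pytest.approx(-1.0)

    def test_textbook_rank_example(self):
        # 1 - 6*sum(d^2)/(n(n^2-1)) = 1 - 12/60 = 0.8
        res = spearman([1, 2, 3, 4], [1, 3, 2, 4], ci=False)
        assert res.r == pytest.approx(0.8)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_bootstrap_ci_brackets_estimate(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=80)
        y = x + rng.normal(scale=0.7, size=80)
        res = spearman(x, y, B=300, rng=3)
        assert res.ci[0] <= res.r <= res.ci[1]


class TestDeLong:
    def test_identical_scores_p_one(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8])
        labels = np.array([0, 1, 0, 1])
        res = delong_compare(scores, scores, labels)
        assert res.auc_diff == 0.0
        assert res.p == 1.0

    def test_placements_match_enumeration_oracle(self):
        rng = np.random.default_rng(9)
        from ptaupet.evaluate import _placements

        for _ in range(25):
            scores, labels = random_instance(rng, 20)
            v10, v01, auc = _placements(scores, labels)
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            psi = (pos[:, None] > neg[None, :]) + 0.5 * (
                pos[:, None] == neg[None, :]
            )
            assert np.allclose(v10, psi.mean(axis=1))
            assert np.allclose(v01, psi.mean(axis=0))
            assert auc == pytest.approx(psi.mean())

    def test_four_record_variance_hand_calculation(self):
        # pos {3, 1}, neg {2, 0} for model a; model b reverses one pair
        a = np.array([3.0, 1.0, 2.0, 0.0])
        b = np.array([3.0, 2.5, 2.0, 0.0])
        labels = np.array([1, 1, 0, 0])
        # placements a: V10 = [1, 0.5], V01 = [0.5, 1]; AUC_a = 0.75
        # placements b: V10 = [1, 1],  V01 = [1, 1];  AUC_b = 1.0
        res = delong_compare(a, b, labels)
        assert res.auc_a == pytest.approx(0.75)
        assert res.auc_b == pytest.approx(1.0)
        s10 = np.cov([[1, 0.5], [1, 1]], ddof=1)
        s01 = np.cov([[0.5, 1], [1, 1]], ddof=1)
        expected_var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / 2 + (
            s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
        ) / 2
        assert res.variance == pytest.approx(expected_var)

    def test_null_type_one_error_calibrated(self):
        # both scores pure noise: rejection rate at alpha=0.05 stays within
        # binomial error over 800 simulations
        rng = np.random.default_rng(10)
        rejections = 0
        n_sim = 800
        for _ in range(n_sim):
            labels = np.array([1] * 50 + [0] * 50)
            res = delong_compare(
                rng.normal(size=100), rng.normal(size=100), labels
            )
            rejections += res.p < 0.05
        rate = rejections / n_sim
        assert abs(rate - 0.05) < 3 * math.sqrt(0.05 * 0.95 / n_sim)

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValueError, match="aligned"):
            delong_compare([1.0, 2.0], [1.0], [1, 0])


class TestLogistic:
    def test_single_feature_preserves_ranks(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=60)
        y = (rng.random(60) < 1 / (1 + np.exp(-x))).astype(int)
        fit = fit_logistic(x, y)
        assert roc_curve(fit.predicted, y).auc == pytest.approx(
            roc_curve(x, y).auc, abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            fit_logistic(np.arange(5.0), np.ones(5))

    def test_newton_raphson_oracle_eight_records(self):
        x = np.array([0.2, 0.6, 1.0, 1.4, 1.8, 2.2, 2.6, 3.0])
        y = np.array([0, 0, 1, 0, 1, 1, 0, 1])
        fit = fit_logistic(x, y)
        # independent Newton-Raphson oracle on the same likelihood
        X = np.column_stack([np.ones(8), x])
        beta = np.zeros(2)
        for _ in range(60):
            eta = X @ beta
            mu = 1 / (1 + np.exp(-eta))
            grad = X.T @ (y - mu)
            hess = X.T @ (X * (mu * (1 - mu))[:, None])
            step = np.linalg.solve(hess, grad)
            beta = beta + step
            if np.abs(step).max() < 1e-12:
                break
        assert np.allclose(fit.coefficients, beta, atol=1e-6)
        assert not fit.separation

    def test_complete_separation_flagged(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 10.0, 11.0, 12.0, 13.0])
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        fit = fit_logistic(x, y)
        assert fit.separation

    def test_singular_design_rejected(self):
        X = np.column_stack([np.arange(8.0), np.arange(8.0)])
        y = np.array([0, 1, 0, 1, 0, 1, 0, 1])
        with pytest.raises(ValueError, match="singular"):
            fit_logistic(X, y)


class TestTwoThresholdTriage:
    def test_hand_enumeration(self):
        scores = np.array([0.10, 0.15, 0.20, 0.30])
        labels = np.array([0, 1, 0, 1])
        zc = two_threshold_classify(scores, labels, 0.14, 0.23)
        assert list(zc.zones) == ["Low", "Indeterminate", "Indeterminate", "High"]
        assert zc.pct_low_correct == 1.0
        assert zc.pct_high_correct == 1.0
        assert zc.overall_correct == 1.0
        assert zc.frac_ind == pytest.approx(0.5)

    def test_boundary_values_are_indeterminate(self):
        zc = two_threshold_classify([0.14, 0.23], [0, 1], 0.14, 0.23)
        assert list(zc.zones) == ["Indeterminate", "Indeterminate"]

    def test_degenerate_equal_thresholds(self):
        zc = two_threshold_classify([0.1, 0.9], [0, 1], 0.5, 0.5)
        assert zc.frac_ind == 0.0
        assert zc.overall_correct == 1.0

    def test_all_low_all_negative(self):
        zc = two_threshold_classify([0.1, 0.05], [0, 0], 0.2, 0.3)
        assert zc.frac_low == 1.0
        assert zc.overall_correct == 1.0
        assert zc.pct_high_correct is None

    def test_reversed_thresholds_rejected(self):
        with pytest.raises(ValueError, match="lower"):
            two_threshold_classify([0.1], [1], 0.3, 0.2)

    @given(
        lower=st.floats(-1, 1),
        width1=st.floats(0, 1),
        width2=st.floats(0, 1),
        seed=st.integers(0, 500),
    )
    @settings(max_examples=80, deadline=None)
    def test_fractions_sum_and_interval_nesting(self, lower, width1, width2, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=30)
        labels = (rng.random(30) < 0.5).astype(int)
        narrow = two_threshold_classify(scores, labels, lower, lower + width1)
        wide = two_threshold_classify(
            scores, labels, lower, lower + width1 + width2
        )
        for zc in (narrow, wide):
            assert zc.frac_low + zc.frac_ind + zc.frac_high == pytest.approx(
                1.0, abs=1e-12
            )
        assert narrow.frac_ind <= wide.frac_ind + 1e-12


class TestGroupComparisons:
    def test_identical_groups_no_signal(self):
        values = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = compare_groups({"a": values, "b": values, "c": values})
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert not res.pairwise["reject"].any()

    def test_shifted_groups_detected_with_power(self):
        # two groups 1.5 pooled-SD apart at n=15: Tukey flags the pair in
        # >= 90% of simulations
        rng = np.random.default_rng(12)
        hits = 0
        n_sim = 400
        for _ in range(n_sim):
            a = rng.normal(0.0, 1.0, 15)
            b = rng.normal(1.5, 1.0, 15)
            res = compare_groups({"a": a, "b": b})
            hits += bool(res.pairwise["reject"].iloc[0])
        assert hits / n_sim >= 0.90

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="need >= 3"):
            compare_groups({"a": [1.0, 2.0], "b": [1.0, 2.0, 3.0]})

    def test_skewed_data_selects_kruskal(self):
        rng = np.random.default_rng(13)
        res = compare_groups(
            {
                "a": rng.lognormal(0, 1.2, 60),
                "b": rng.lognormal(0.3, 1.2, 60),
            }
        )
        assert res.test == "kruskal"

    def test_chi_square_hand_example(self):
        stat, p, dof = chi_square([[10, 0], [0, 10]])
        assert stat == pytest.approx(20.0)
        assert dof == 1
        assert p == pytest.approx(7.7e-6, rel=0.01)


class TestEffectSizeAndPower:
    def test_identical_groups_zero_effect(self):
        assert cohens_d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(0.0)

    def test_hand_computed_effect(self):
        assert cohens_d([1.0, 2.0, 3.0], [2.0, 3.0, 4.0]) == pytest.approx(-1.0)

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError, match="pooled SD"):
            cohens_d([2.0, 2.0], [2.0, 2.0])

    def test_zero_effect_power_is_alpha(self):
        assert power_two_sample(50, 0.0, alpha=0.05) == pytest.approx(0.05, abs=1e-6)

    def test_large_n_power_saturates(self):
        assert power_two_sample(10_000, 1.5) == pytest.approx(1.0, abs=1e-9)

    def test_minimum_subgroup_size_reaches_90pct_power(self):
        assert power_two_sample(15, 1.5, alpha=0.05) >= 0.90

    def test_bad_alpha_rejected(self):
        with pytest.raises(ValueError, match="alpha"):
            power_two_sample(15, 1.5, alpha=1.5)


class TestBonferroni:
    def test_adjustment_and_cap(self):
        adjusted = bonferroni([0.01, 0.2, 0.5])
        assert adjusted == pytest.approx([0.03, 0.6, 1.0])

    @given(
        p=st.lists(st.floats(0, 1), min_size=2, max_size=10),
    )
    @settings(max_examples=60, deadline=None)
    def test_monotone_in_p(self, p):
        adjusted = bonferroni(sorted(p))
        assert (np.diff(adjusted) >= -1e-12).all()
        assert ((0 <= adjusted) & (adjusted <= 1)).all()
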