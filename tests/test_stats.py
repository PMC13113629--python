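"""Nonparametric battery: rank correlation, U test, HL shift + CI, ROC."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from petmr_hybrid.quantify import FEATURE_NAMES
from petmr_hybrid.stats import (
    DEFAULT_CI_LEVEL,
    _u_counts,
    bonferroni,
    correction_factors,
    hl_confidence_interval,
    hodges_lehmann,
    mann_whitney,
    roc_analysis,
    run_univariate_battery,
    spearman,
)


def exact_mw_p(x, y):
    """Independent oracle: enumerate every assignment of the pooled sample."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    u_obs = sum((xi > yj) + 0.5 * (xi == yj) for xi in x for yj in y)
    mu = n1 * len(y) / 2
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        u = sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys)
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
        total += 1
    return count / total


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(12.0)
        assert spearman(x, x**3)[0] == pytest.approx(1.0)
        assert spearman(x, -x)[0] == pytest.approx(-1.0)

    def test_equals_pearson_on_average_ranks_with_ties(self, rng):
        x = rng.integers(0, 5, 30).astype(float)  # heavy ties
        y = x + rng.integers(0, 3, 30)
        rho, _ = spearman(x, y)
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        assert rho == pytest.approx(np.corrcoef(rx, ry)[0, 1], abs=1e-12)

    def test_matches_scipy_rho(self, rng):
        x, y = rng.random(40), rng.random(40)
        rho, p = spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_exact_permutation_p_perfect_order_n5(self):
        # among 5! pairings exactly two reach |rho| = 1
        x = np.array([1.0, 2, 3, 4, 5])
        _, p = spearman(x, 2 * x)
        assert p == pytest.approx(2 / 120)

    def test_constant_vector_flagged(self):
        rho, p = spearman(np.ones(5), np.arange(5.0))
        assert math.isnan(rho) and math.isnan(p)


class TestMannWhitney:
    def test_extreme_separation_exact_p(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2/20 assignments as extreme

    def test_identical_groups_symmetric(self, rng):
        x = rng.random(25)
        _, p = mann_whitney(x, x)
        assert p > 0.9

    def test_u_sum_identity(self, rng):
        x, y = rng.random(13), rng.random(9)
        ux, _ = mann_whitney(x, y)
        uy, _ = mann_whitney(y, x)
        assert ux + uy == pytest.approx(13 * 9)

    @pytest.mark.parametrize("n1,n2", [(2, 3), (4, 4), (3, 6), (5, 5)])
    def test_exact_p_matches_enumeration(self, n1, n2, rng):
        x = rng.normal(0, 1, n1)
        y = rng.normal(0.8, 1, n2)
        _, p = mann_whitney(x, y)
        assert p == pytest.approx(exact_mw_p(x, y), abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestHodgesLehmann:
    def test_small_example(self):
        assert hodges_lehmann([1, 2, 3], [0]) == 2.0

    def test_location_model_shift_recovered(self, rng):
        y = rng.random(20)
        assert hodges_lehmann(y + 3.25, y) == pytest.approx(3.25)

    def test_matches_exhaustive_pairing_oracle(self, rng):
        x, y = rng.normal(size=9), rng.normal(size=7)
        diffs = sorted(xi - yj for xi in x for yj in y)
        assert hodges_lehmann(x, y) == pytest.approx(float(np.median(diffs)))


class TestHlConfidenceInterval:
    def test_u_distribution_counts(self):
        # frequencies must sum to C(n1+n2, n1) and be symmetric
        for n1, n2 in [(3, 1), (4, 5), (2, 7)]:
            counts = _u_counts(n1, n2)
            assert sum(counts) == math.comb(n1 + n2, n1)
            assert counts == counts[::-1]
            assert len(counts) == n1 * n2 + 1

    def test_degenerate_small_sample_full_range(self):
        lo, hi = hl_confidence_interval([1, 2, 3], [0], level=0.998)
        assert (lo, hi) == (1.0, 3.0)

    def test_level_one_limit_gives_min_max(self, rng):
        x, y = rng.random(8), rng.random(8)
        lo, hi = hl_confidence_interval(x, y, level=1 - 1e-12)
        diffs = np.subtract.outer(x, y)
        assert lo == pytest.approx(diffs.min()) and hi == pytest.approx(diffs.max())

    def test_endpoints_are_pairwise_differences_and_bracket_hle(self, rng):
        x, y = rng.normal(1, 1, 12), rng.normal(0, 1, 10)
        lo, hi = hl_confidence_interval(x, y, 0.95)
        diffs = np.subtract.outer(x, y).ravel()
        assert np.isclose(diffs, lo).any() and np.isclose(diffs, hi).any()
        assert lo <= hodges_lehmann(x, y) <= hi

    def test_shift_equivariance(self, rng):
        x, y = rng.normal(size=10), rng.normal(size=10)
        lo, hi = hl_confidence_interval(x, y, 0.99)
        lo2, hi2 = hl_confidence_interval(x + 5, y + 5, 0.99)
        assert lo2 == pytest.approx(lo) and hi2 == pytest.approx(hi)

    def test_matches_exact_order_statistic_construction(self, rng):
        # independent recomputation of the Moses interval from the exact U cdf
        x, y = rng.normal(size=6, loc=1), rng.normal(size=5)
        level = 0.95
        counts = np.array(_u_counts(6, 5), float)
        cdf = np.cumsum(counts) / counts.sum()
        ks = np.flatnonzero(cdf <= 0.025 + 1e-12)
        k = ks[-1]
        diffs = np.sort(np.subtract.outer(x, y).ravel())
        assert hl_confidence_interval(x, y, level) == (diffs[k], diffs[len(diffs) - 1 - k])

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError):
            hl_confidence_interval([1], [2], level=1.2)


class TestBonferroni:
    @pytest.mark.parametrize("p,factor,expected", [(0.001, 23, 0.023), (0.1, 23, 1.0), (0.5, 1, 0.5)])
    def test_adjustment_and_cap(self, p, factor, expected):
        assert bonferroni(p, factor) == pytest.approx(expected)

    def test_factors_from_inventory(self):
        assert correction_factors(9, 14) == (126, 23)
        assert correction_factors() == (126, 23)

    def test_monotone_in_factor(self):
        assert bonferroni(0.01, 9) <= bonferroni(0.01, 23) <= bonferroni(0.01, 126)


class TestRoc:
    def test_perfect_separation(self):
        res = roc_analysis([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1], +1)
        assert res.auc == 1.0
        assert res.sensitivity == 100.0 and res.specificity == 100.0
        assert 3 < res.cutoff < 10
        assert res.ppv == 100.0 and res.npv == 100.0

    def test_auc_equals_u_statistic_identity(self, rng):
        scores = rng.random(60)
        labels = rng.integers(0, 2, 60)
        if labels.sum() in (0, 60):
            labels[0] = 1 - labels[0]
        res = roc_analysis(scores, labels, +1)
        u, _ = mann_whitney(scores[labels == 1], scores[labels == 0])
        assert res.auc == pytest.approx(u / (labels.sum() * (60 - labels.sum())), abs=1e-12)

    def test_orientation_flip_mirrors_auc(self, rng):
        scores = rng.random(40)
        labels = (scores + rng.normal(0, 0.3, 40) > 0.5).astype(int)
        if labels.sum() in (0, 40):
            labels[0] = 1 - labels[0]
        a1 = roc_analysis(scores, labels, +1).auc
        a2 = roc_analysis(scores, labels, -1).auc
        assert a1 + a2 == pytest.approx(1.0)

    def test_ppv_npv_bayes_consistency(self, rng):
        scores = rng.random(80)
        labels = (scores + rng.normal(0, 0.4, 80) > 0.5).astype(int)
        res = roc_analysis(scores, labels, +1)
        prev = labels.mean()
        se, sp = res.sensitivity / 100, res.specificity / 100
        expected_ppv = se * prev / (se * prev + (1 - sp) * (1 - prev))
        assert res.ppv == pytest.approx(100 * expected_ppv, abs=1e-9)

    def test_cutoff_attains_max_youden(self, rng):
        scores = rng.normal(size=50)
        labels = (scores + rng.normal(0, 1, 50) > 0).astype(int)
        res = roc_analysis(scores, labels, +1)
        pos, neg = scores[labels == 1], scores[labels == 0]
        best = max(
            ((pos >= c).mean() + (neg < c).mean() - 1)
            for c in np.concatenate([scores - 1e-9, scores + 1e-9])
        )
        j = res.sensitivity / 100 + res.specificity / 100 - 1
        assert j == pytest.approx(best, abs=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis([1, 2, 3], [1, 1, 1], +1)

    def test_delong_ci_brackets_auc(self, rng):
        scores = rng.random(50)
        labels = rng.integers(0, 2, 50)
        labels[:5] = 1
        labels[-5:] = 0
        res = roc_analysis(scores, labels, +1)
        assert 0 <= res.auc_ci_low <= res.auc <= res.auc_ci_high <= 1


class TestBattery:
    def test_output_inventory(self, default_cohort):
        from petmr_hybrid.pipeline import RunConfig, extract_features_table

        features, _ = extract_features_table(default_cohort, RunConfig())
        res = run_univariate_battery(features, default_cohort)
        assert set(res.comparisons["contrast"]) == {
            "G1 vs G2", "G1 vs G3", "G2 vs G3", "Ki67- vs Ki67+", "luminalA vs luminalB"
        }
        for contrast, sub in res.comparisons.groupby("contrast"):
            assert len(sub) == 23
        assert len(res.correlations) == 23 * 3
        assert len(res.cross_correlations) == 126
        assert (res.cross_correlations["correction_factor"] == 126).all()
        assert (res.comparisons["p_adjusted"] >= res.comparisons["p_raw"] - 1e-15).all()
        assert (res.comparisons["ci_low"] <= res.comparisons["hle"]).all()
        assert (res.comparisons["hle"] <= res.comparisons["ci_high"]).all()

    def test_hle_sign_convention_on_effect_cohort(self, default_cohort):
        # SUV rises with aggressiveness, so reference-minus-aggressive is negative
        from petmr_hybrid.pipeline import RunConfig, extract_features_table

        features, _ = extract_features_table(default_cohort, RunConfig())
        res = run_univariate_battery(features, default_cohort, do_roc=False, do_cross_correlations=False)
        row = res.comparisons.query("parameter == 'SUVmean' and contrast == 'G1 vs G3'").iloc[0]
        assert row["hle"] < 0
        adc = res.comparisons.query("parameter == 'ADCmin' and contrast == 'G1 vs G3'").iloc[0]
        assert adc["hle"] > 0

    def test_duplicated_feature_gives_identical_statistics(self, default_cohort):
        from petmr_hybrid.pipeline import RunConfig, extract_features_table

        features, _ = extract_features_table(default_cohort, RunConfig())
        features = features.copy()
        features["SUVmax*E1"] = features["SUVmax"]  # impostor hybrid
        res = run_univariate_battery(features, default_cohort, do_roc=False, do_cross_correlations=False, contrasts=["Ki67- vs Ki67+"])
        a = res.comparisons.query("parameter == 'SUVmax'").iloc[0]
        b = res.comparisons.query("parameter == 'SUVmax*E1'").iloc[0]
        assert a["p_raw"] == b["p_raw"] and a["hle"] == b["hle"]
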