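"""Normality routing, group tests, paired t, ROC and ICC."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from dcekin import (
    compare_groups,
    grade_icc,
    icc_agreement,
    ks_normality,
    paired_t,
    roc_auc,
)


class TestKsNormality:
    def test_normal_sample_passes(self):
        x = np.random.default_rng(0).normal(size=5000)
        _, _, is_normal = ks_normality(x)
        assert is_normal

    def test_exponential_sample_fails(self):
        x = np.random.default_rng(0).exponential(size=5000)
        _, _, is_normal = ks_normality(x)
        assert not is_normal

    def test_statistic_matches_step_enumeration(self):
        """D on {-1, 0, 1} = max |ECDF - Phi_hat| over the three step points."""
        x = np.array([-1.0, 0.0, 1.0])
        d, _, _ = ks_normality(x)
        cdf = sps.norm(loc=x.mean(), scale=x.std(ddof=1)).cdf
        brute = max(
            max(abs(i / 3 - cdf(v)), abs((i + 1) / 3 - cdf(v)))
            for i, v in enumerate(sorted(x))
        )
        assert d == pytest.approx(brute, abs=1e-12)

    def test_zero_variance_not_normal(self):
        _, _, is_normal = ks_normality([2.0, 2.0, 2.0])
        assert not is_normal


class TestCompareGroups:
    def test_small_separated_groups_exact_mannwhitney(self):
        """{1,2,3} vs {4,5,6}: U = 0, exact two-sided p = 2/20 = 0.1."""
        res = compare_groups([1, 2, 3], [4, 5, 6])
        assert res.route == "nonparametric"
        assert res.statistic == 0.0
        # oracle: enumerate all C(6,3) = 20 assignments of ranks to group A
        obs_u = 0
        count_extreme = 0
        for combo in itertools.combinations(range(1, 7), 3):
            u = sum(1 for a in combo for b in set(range(1, 7)) - set(combo) if a > b)
            u = min(u, 9 - u)
            if u <= obs_u:
                count_extreme += 1
        assert res.p_value == pytest.approx(count_extreme / 20)
        assert res.p_value == pytest.approx(0.1)

    def test_identical_groups_no_effect(self):
        res = compare_groups([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert res.p_value >= 0.99

    def test_welch_statistic_closed_form(self):
        """{1,2,3} vs {2,4,6}: t = (2-4)/sqrt(1/3 + 4/3) = -1.5492."""
        a, b = np.array([1.0, 2, 3]), np.array([2.0, 4, 6])
        t_closed = (a.mean() - b.mean()) / np.sqrt(a.var(ddof=1) / 3 + b.var(ddof=1) / 3)
        res = sps.ttest_ind(a, b, equal_var=False)
        assert res.statistic == pytest.approx(t_closed)
        # two KS-normal larger groups take the parametric route
        rng = np.random.default_rng(14)
        ga, gb = rng.normal(0, 1, 20), rng.normal(1.5, 1, 20)
        routed = compare_groups(ga, gb)
        assert routed.route == "parametric"
        t_big = (ga.mean() - gb.mean()) / np.sqrt(
            ga.var(ddof=1) / 20 + gb.var(ddof=1) / 20
        )
        assert routed.statistic == pytest.approx(t_big)

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [2.0, 3.0])

    def test_large_sample_tie_corrected_normal_approximation(self):
        rng = np.random.default_rng(5)
        a = np.round(rng.normal(0, 1, 30), 1)
        b = np.round(rng.normal(1, 1, 30), 1)
        res = compare_groups(a, b)
        assert 0 <= res.p_value <= 1


class TestPairedT:
    def test_closed_form(self):
        """Differences {1,2,3}: t = 2 / (1/sqrt(3)) = 3.4641, p = 0.0742."""
        res = paired_t([1.0, 2, 3], [2.0, 4, 6])
        assert res.statistic == pytest.approx(-3.4641, abs=1e-4)
        assert res.p_value == pytest.approx(0.0742, abs=1e-4)

    def test_zero_variance_degenerate(self):
        with pytest.raises(ValueError, match="zero variance"):
            paired_t([1.0, 2, 3], [1.0, 2, 3])

    def test_translation_invariance(self):
        r1 = paired_t([1.0, 2, 4], [2.0, 4, 5])
        r2 = paired_t([11.0, 12, 14], [12.0, 14, 15])
        assert r1.statistic == pytest.approx(r2.statistic)


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1])
        assert res.auc == 1.0
        assert res.orientation == "higher"

    def test_all_ties_give_half(self):
        res = roc_auc([5.0] * 6, [0, 0, 0, 1, 1, 1])
        assert res.auc == 0.5

    def test_pair_counting_oracle(self):
        """Positives {3, 1}, negatives {2, 0}: 3 of 4 pairs concordant."""
        scores = [3.0, 1.0, 2.0, 0.0]
        labels = [1, 1, 0, 0]
        res = roc_auc(scores, labels)
        wins = sum(
            (p > n) + 0.5 * (p == n)
            for p in (3.0, 1.0) for n in (2.0, 0.0)
        )
        assert res.auc == pytest.approx(wins / 4) == pytest.approx(0.75)

    @given(st.lists(st.floats(-5, 5), min_size=4, max_size=20))
    def test_antisymmetry_under_negation(self, scores):
        labels = [i % 2 for i in range(len(scores))]
        a1 = roc_auc(scores, labels).auc
        a2 = roc_auc([-s for s in scores], labels).auc
        assert a1 + a2 == pytest.approx(1.0)

    def test_equals_mannwhitney_u_relation(self):
        rng = np.random.default_rng(9)
        pos = rng.normal(1, 1, 8)
        neg = rng.normal(0, 1, 11)
        scores = np.concatenate([pos, neg])
        labels = np.concatenate([np.ones(8), np.zeros(11)])
        u = sps.mannwhitneyu(pos, neg, alternative="two-sided").statistic
        assert roc_auc(scores, labels).auc == pytest.approx(u / (8 * 11))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [1, 1])


class TestIcc:
    def test_perfect_agreement(self):
        mat = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0], [4.0, 4.0]])
        res = icc_agreement(mat)
        assert res.icc == pytest.approx(1.0)
        assert res.category == "excellent"

    def test_matches_anova_mean_squares_closed_form(self):
        """4 subjects x 2 readers against the two-way random-effects formula."""
        mat = np.array([[9.0, 2.0], [4.5, 4.0], [6.1, 6.9], [8.0, 7.0]])
        n, k = mat.shape
        grand = mat.mean()
        ms_rows = k * ((mat.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        ms_cols = n * ((mat.mean(axis=0) - grand) ** 2).sum() / (k - 1)
        resid = mat - mat.mean(axis=1, keepdims=True) - mat.mean(axis=0, keepdims=True) + grand
        ms_err = (resid ** 2).sum() / ((n - 1) * (k - 1))
        icc_closed = (ms_rows - ms_err) / (
            ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n
        )
        res = icc_agreement(mat)
        assert res.icc == pytest.approx(icc_closed, abs=1e-6)

    @pytest.mark.parametrize(
        "icc,category",
        [(0.95, "excellent"), (0.81, "excellent"), (0.70, "good"), (0.61, "good"),
         (0.5, "moderate"), (0.3, "fair"), (0.1, "poor"), (-0.4, "poor")],
    )
    def test_grading_bands(self, icc, category):
        assert grade_icc(icc) == category

    @given(st.floats(-1.0, 1.0))
    def test_grading_exhaustive_over_range(self, icc):
        assert grade_icc(icc) in {"excellent", "good", "moderate", "fair", "poor"}

    def test_missing_cells_rejected(self):
        mat = np.array([[1.0, np.nan], [2.0, 2.0], [3.0, 3.0]])
        with pytest.raises(ValueError, match="missing"):
            icc_agreement(mat)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            icc_agreement(np.array([[1.0, 1.0], [2.0, 2.0]]))
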