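"""Finite chance level, t-tests, BH-FDR, joint significance, ANOVA."""

import numpy as np
import pytest
from scipy import stats as sps

from ecogdecode.stats import (AnovaResult, ChanceSpec, FeatureResult,
                              anova_roi_band, bh_fdr, finite_chance_level,
                              joint_significance, ttest_accuracy,
                              ttest_meandiff)


def _chance_by_summation(n, c, alpha):
    """Independent oracle: explicit binomial tail summation."""
    p = 1.0 / c
    # P(X >= k) computed by direct summation of the pmf
    for k in range(n + 1):
        tail = sum(sps.binom.pmf(j, n, p) for j in range(k, n + 1))
        if tail <= alpha:
            return k / n
    return 1.0


class TestFiniteChanceLevel:
    def test_large_n_approaches_theoretical_chance(self):
        thr = finite_chance_level(ChanceSpec(n_test=10**6, n_classes=2))
        assert abs(thr - 0.5) < 0.002

    @pytest.mark.parametrize("n,c,alpha", [(100, 2, 0.05), (20, 3, 0.05),
                                           (50, 2, 0.01), (35, 3, 0.01)])
    def test_matches_binomial_summation_oracle(self, n, c, alpha):
        thr = finite_chance_level(ChanceSpec(n, c, alpha))
        assert thr == pytest.approx(_chance_by_summation(n, c, alpha))

    def test_decreasing_trend_and_above_theoretical(self):
        # the threshold always exceeds 1/c and trends down with n
        # (binomial discreteness allows one-count local jitter)
        prev = 1.0
        for n in range(10, 200, 10):
            thr = finite_chance_level(ChanceSpec(n, 2, 0.05))
            assert thr > 0.5
            assert thr <= prev + 1.0 / n
            prev = thr
        assert finite_chance_level(ChanceSpec(190, 2, 0.05)) \
            < finite_chance_level(ChanceSpec(10, 2, 0.05))


class TestTtests:
    def test_values_at_chance_give_p_one(self):
        assert ttest_accuracy([0.6, 0.6, 0.6, 0.60001, 0.59999], 0.6) \
            == pytest.approx(1.0, abs=0.01)

    def test_closed_form_t(self):
        # mean .7, sd .1, n=3 vs 0.5: t = 0.2/(0.1/sqrt(3)) = 3.4641
        p = ttest_accuracy([0.6, 0.7, 0.8], 0.5)
        t = 0.2 / (0.1 / np.sqrt(3))
        assert p == pytest.approx(2 * sps.t.sf(t, df=2), rel=1e-9)

    def test_far_from_null_tiny_p(self):
        rng = np.random.default_rng(0)
        accs = 0.9 + rng.normal(0, 1e-3, size=35)
        assert ttest_accuracy(accs, 0.5) < 1e-10

    def test_symmetric_diffs_give_p_one(self):
        assert ttest_meandiff([-1.0, 1.0]) == pytest.approx(1.0)

    def test_consistent_positive_diffs_significant(self):
        rng = np.random.default_rng(1)
        assert ttest_meandiff(1.0 + rng.normal(0, 0.05, 35)) < 1e-10

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            ttest_meandiff([0.5])

    def test_zero_variance_flagged_as_nan(self):
        assert np.isnan(ttest_accuracy([0.9, 0.9, 0.9], 0.5))


def _bh_bruteforce(pvals, alpha):
    """Direct evaluation of the step-up rule definition."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.sort(p)
    k_p = None
    for i in range(1, n + 1):
        if order[i - 1] <= i / n * alpha:
            k_p = order[i - 1]
    if k_p is None:
        return np.zeros(n, dtype=bool)
    return p <= k_p


class TestBhFdr:
    def test_hand_worked_example(self):
        rej = bh_fdr([0.001, 0.02, 0.03, 0.5], alpha=0.05)
        np.testing.assert_array_equal(rej, [True, True, True, False])

    def test_all_ones_reject_nothing(self):
        assert not bh_fdr([1.0] * 10, alpha=0.05).any()

    def test_matches_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 30))
            if rng.random() < 0.5:
                p = p ** 3  # push some toward significance
            np.testing.assert_array_equal(bh_fdr(p, 0.05),
                                          _bh_bruteforce(p, 0.05))

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(8)
        for _ in range(50):
            p = rng.uniform(size=40) ** 2
            ours = bh_fdr(p, 0.01)
            ref = multipletests(p, alpha=0.01, method="fdr_bh")[0]
            np.testing.assert_array_equal(ours, ref)

    def test_order_invariance(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=20) ** 2
        perm = rng.permutation(20)
        np.testing.assert_array_equal(bh_fdr(p, 0.05)[perm],
                                      bh_fdr(p[perm], 0.05))

    def test_rejections_monotone_in_alpha(self):
        rng = np.random.default_rng(10)
        p = rng.uniform(size=30) ** 2
        r1 = bh_fdr(p, 0.01)
        r5 = bh_fdr(p, 0.05)
        assert np.all(r5[r1])  # everything rejected at 0.01 also at 0.05


class TestBhFdrProperties:
    """Structural invariants of the step-up rule, property-based."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40),
           st.sampled_from([0.01, 0.05, 0.10]))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_rejection_set_is_a_pvalue_prefix(self, pvals, alpha):
        rej = bh_fdr(pvals, alpha)
        p = np.asarray(pvals)
        if rej.any() and (~rej).any():
            assert p[rej].max() <= p[~rej].min()
        if rej.any():
            # every rejected p satisfies the step-up bound at its rank
            k = rej.sum()
            assert np.sort(p)[k - 1] <= k / p.size * alpha

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_monotone_in_alpha(self, pvals):
        r_small = bh_fdr(pvals, 0.01)
        r_large = bh_fdr(pvals, 0.05)
        assert np.all(r_large[r_small])


class TestChanceLevelProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.integers(2, 400), st.integers(2, 4),
           st.sampled_from([0.05, 0.01]))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_threshold_is_the_smallest_valid_count(self, n, c, alpha):
        thr = finite_chance_level(ChanceSpec(n, c, alpha))
        k = int(round(thr * n))
        assert thr > 1.0 / c
        assert sps.binom.sf(k - 1, n, 1.0 / c) <= alpha + 1e-12
        if k > 1:
            assert sps.binom.sf(k - 2, n, 1.0 / c) > alpha


def _result(roi, band, accs, diffs, p_acc, p_diff):
    r = FeatureResult(roi=roi, band=band,
                      accuracies=np.asarray(accs, dtype=float),
                      mean_diffs=np.asarray(diffs, dtype=float))
    r.p_acc, r.p_diff = p_acc, p_diff
    return r


class TestJointSignificance:
    def test_accuracy_only_is_not_joint(self):
        results = [_result("r", "b", [0.9] * 5, [0.0] * 5, 1e-8, 0.9),
                    _result("r2", "b", [0.5] * 5, [0.0] * 5, 0.8, 0.7)]
        joint_significance(results, alpha=0.01, chance=0.6)
        assert results[0].sig_acc and not results[0].sig_diff
        assert not results[0].sig_joint

    def test_both_families_rejecting_gives_joint(self):
        results = [_result("r", "b", [0.9] * 5, [1.0] * 5, 1e-8, 1e-9)]
        joint_significance(results, alpha=0.01, chance=0.6)
        assert results[0].sig_joint

    def test_below_chance_accuracy_not_flagged(self):
        # a two-sided t-test also fires below the chance threshold;
        # that must not count as decodable
        results = [_result("r", "b", [0.50] * 5, [1.0] * 5, 1e-8, 1e-9)]
        joint_significance(results, alpha=0.01, chance=0.6)
        assert not results[0].sig_acc


class TestAnova:
    def test_equal_accuracies_give_zero_f(self):
        records = [(r, b, 0.7) for r in "AB" for b in "xy" for _ in range(3)]
        res = anova_roi_band(records)
        assert res.f_roi == 0.0 and res.f_band == 0.0
        assert res.f_interaction == 0.0
        assert res.p_roi == 1.0

    def test_matches_textbook_sum_of_squares(self):
        # balanced 2x2 with n=3: classical two-way decomposition
        rng = np.random.default_rng(11)
        records = []
        vals = {}
        for r in "AB":
            for b in "xy":
                v = rng.normal(0.6 + 0.1 * (r == "B") + 0.05 * (b == "y"),
                               0.02, size=3)
                vals[(r, b)] = v
                records += [(r, b, x) for x in v]
        res = anova_roi_band(records)

        allv = np.concatenate(list(vals.values()))
        grand = allv.mean()
        m_r = {r: np.concatenate([vals[(r, b)] for b in "xy"]).mean()
               for r in "AB"}
        m_b = {b: np.concatenate([vals[(r, b)] for r in "AB"]).mean()
               for b in "xy"}
        ss_roi = 6 * sum((m_r[r] - grand) ** 2 for r in "AB")
        ss_band = 6 * sum((m_b[b] - grand) ** 2 for b in "xy")
        ss_int = 3 * sum((vals[(r, b)].mean() - m_r[r] - m_b[b] + grand) ** 2
                         for r in "AB" for b in "xy")
        ss_err = sum(((vals[(r, b)] - vals[(r, b)].mean()) ** 2).sum()
                     for r in "AB" for b in "xy")
        f_roi = (ss_roi / 1) / (ss_err / 8)
        f_band = (ss_band / 1) / (ss_err / 8)
        f_int = (ss_int / 1) / (ss_err / 8)
        assert res.f_roi == pytest.approx(f_roi, rel=1e-8)
        assert res.f_band == pytest.approx(f_band, rel=1e-8)
        assert res.f_interaction == pytest.approx(f_int, rel=1e-8)
        assert res.df == (1.0, 1.0, 1.0, 8.0)

    def test_injected_roi_effect_detected(self):
        # additive ROI effect, no band effect: averaged over seeds the
        # ROI p-value is small and the band p-value is not
        p_rois, p_bands = [], []
        for seed in range(8):
            rng = np.random.default_rng(100 + seed)
            records = []
            for i, r in enumerate("ABCD"):
                for b in "vwxyz":
                    records += [(r, b, x) for x in
                                rng.normal(0.6 + 0.05 * i, 0.05, size=7)]
            res = anova_roi_band(records)
            p_rois.append(res.p_roi)
            p_bands.append(res.p_band)
        assert np.median(p_rois) < 1e-4
        assert np.median(p_bands) > 0.05

    def test_empty_cell_rejected(self):
        records = [("A", "x", 0.5), ("A", "x", 0.6), ("A", "y", 0.5),
                   ("A", "y", 0.6), ("B", "x", 0.5), ("B", "x", 0.6),
                   ("B", "y", 0.7)]
        with pytest.raises(ValueError, match="replicates"):
            anova_roi_band(records)
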