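"""Fold construction, balancing, z-scoring, shared-covariance LDA, and
the per-feature / multiclass / incremental evaluations."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from ecogdecode.containers import DEFAULT_BANDS
from ecogdecode.decode import (FoldScheme, balance_classes, evaluate_feature,
                               evaluate_multiclass, fit_lda_shared,
                               incremental_roi_curve, make_folds, predict_lda,
                               zscore_split)
from ecogdecode.roimap import assign_rois, projection_matrix
from ecogdecode.synth import ElectrodeLayout

from conftest import make_feature_table


class TestMakeFolds:
    def test_buffer_excludes_adjacent_folds(self):
        scheme = make_folds(70, 7, 1)
        assert scheme.train_folds(3) == [0, 1, 5, 6]

    def test_edge_fold_has_one_sided_buffer(self):
        scheme = make_folds(70, 7, 1)
        assert scheme.train_folds(0) == [2, 3, 4, 5, 6]

    def test_zero_buffer_is_plain_kfold(self):
        scheme = make_folds(70, 7, 0)
        assert scheme.train_folds(3) == [0, 1, 2, 4, 5, 6]

    def test_fold_sizes_differ_by_at_most_one(self):
        scheme = make_folds(100, 7, 1)
        sizes = np.bincount(scheme.fold_of_bin)
        assert sizes.max() - sizes.min() <= 1
        assert sizes.sum() == 100

    @pytest.mark.parametrize("n_bins", [70, 101, 144])
    def test_temporal_gap_at_least_one_fold_span(self, n_bins):
        scheme = make_folds(n_bins, 7, 1)
        min_fold = np.bincount(scheme.fold_of_bin).min()
        for k in range(7):
            train, test = scheme.split(k)
            gap = np.abs(train[:, None] - test[None, :]).min()
            assert gap >= min_fold

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            make_folds(10, 7, 1)


class TestBalanceClasses:
    def test_downsamples_to_minority(self):
        labels = np.array(["A"] * 10 + ["B"] * 6, dtype=object)
        kept = balance_classes(np.arange(16), labels, seed=0)
        out = labels[kept]
        assert (out == "A").sum() == 6 and (out == "B").sum() == 6

    def test_balanced_input_unchanged_as_set(self):
        labels = np.array(["A", "B"] * 5, dtype=object)
        kept = balance_classes(np.arange(10), labels, seed=1)
        assert set(kept) == set(range(10))

    def test_three_class_balancing(self):
        labels = np.array(["A"] * 9 + ["B"] * 6 + ["C"] * 3, dtype=object)
        kept = balance_classes(np.arange(18), labels, seed=2)
        out = labels[kept]
        assert all((out == c).sum() == 3 for c in "ABC")

    def test_deterministic_per_seed(self):
        labels = np.array(["A"] * 10 + ["B"] * 4, dtype=object)
        a = balance_classes(np.arange(14), labels, seed=7)
        b = balance_classes(np.arange(14), labels, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_absent_class_named_in_error(self):
        labels = np.array(["A"] * 5, dtype=object)
        with pytest.raises(ValueError, match="B"):
            balance_classes(np.arange(5), labels, seed=0, classes=("A", "B"))


class TestZscoreSplit:
    def test_sample_sd_convention(self):
        train = np.array([[1.0], [2.0], [3.0]])
        test = np.array([[0.0], [10.0]])
        tz, _ = zscore_split(train, test)
        np.testing.assert_allclose(tz[:, 0], [-1.0, 0.0, 1.0])

    def test_test_set_shift_invariant(self):
        rng = np.random.default_rng(5)
        train = rng.normal(size=(20, 3))
        test = rng.normal(size=(10, 3))
        _, z1 = zscore_split(train, test)
        _, z2 = zscore_split(train, test + 100.0)
        np.testing.assert_allclose(z1, z2, atol=1e-9)

    def test_constant_feature_maps_to_zero(self):
        train = np.column_stack([np.arange(5.0), np.full(5, 3.0)])
        test = train.copy()
        tz, sz = zscore_split(train, test)
        np.testing.assert_allclose(tz[:, 1], 0.0)
        np.testing.assert_allclose(sz[:, 1], 0.0)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            zscore_split(np.ones((1, 2)), np.ones((5, 2)))


class TestLda:
    def test_decision_boundary_midpoint_1d(self):
        rng = np.random.default_rng(0)
        X = np.concatenate([rng.normal(0, 1, 500),
                            rng.normal(2, 1, 500)])[:, None]
        y = np.array(["A"] * 500 + ["B"] * 500, dtype=object)
        model = fit_lda_shared(X, y)
        assert predict_lda(model, [[0.9]])[0] == "A"
        assert predict_lda(model, [[1.1]])[0] == "B"

    def test_fitted_means_converge(self):
        rng = np.random.default_rng(1)
        mu = {"A": np.array([0.0, 1.0]), "B": np.array([2.0, -1.0])}
        X = np.vstack([rng.normal(mu["A"], 1.0, size=(2500, 2)),
                       rng.normal(mu["B"], 1.0, size=(2500, 2))])
        y = np.array(["A"] * 2500 + ["B"] * 2500, dtype=object)
        model = fit_lda_shared(X, y)
        np.testing.assert_allclose(model.class_means[0], mu["A"], atol=0.1)
        np.testing.assert_allclose(model.class_means[1], mu["B"], atol=0.1)

    def test_identical_means_give_chance_performance(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(2000, 3))
        y = np.array(["A", "B"] * 1000, dtype=object)
        model = fit_lda_shared(X[:1000], y[:1000])
        acc = np.mean(predict_lda(model, X[1000:]) == y[1000:])
        assert abs(acc - 0.5) < 0.05

    def test_prediction_at_class_mean(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(100, 2))
        y = np.array(["A"] * 50 + ["B"] * 50, dtype=object)
        X[:50] += 3.0
        model = fit_lda_shared(X, y)
        assert predict_lda(model, [model.class_means[1]])[0] == "B"

    def test_tie_goes_to_first_class(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(-1, 1, size=(50, 1)),
                       rng.normal(1, 1, size=(50, 1))])
        y = np.array(["A"] * 50 + ["B"] * 50, dtype=object)
        model = fit_lda_shared(X, y)
        mid = model.class_means.mean(axis=0)
        assert predict_lda(model, [mid])[0] == "A"

    def test_matches_gaussian_density_oracle(self):
        # equal-covariance LDA is the argmax of per-class Gaussian
        # densities with the pooled covariance
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(0, 1, size=(60, 4)),
                       rng.normal(0.8, 1, size=(60, 4))])
        y = np.array(["A"] * 60 + ["B"] * 60, dtype=object)
        model = fit_lda_shared(X, y)
        pts = rng.normal(0.4, 1.5, size=(100, 4))
        dens = np.column_stack([
            multivariate_normal.logpdf(pts, mean=m, cov=model.shared_cov)
            for m in model.class_means])
        oracle = np.array(model.classes, dtype=object)[dens.argmax(axis=1)]
        np.testing.assert_array_equal(predict_lda(model, pts), oracle)

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(40, 3))
        y = np.array(["A"] * 20 + ["B"] * 20, dtype=object)
        model = fit_lda_shared(X, y)
        with pytest.raises(ValueError):
            predict_lda(model, np.zeros((5, 4)))


def _two_roi_assignment():
    pos = np.vstack([np.zeros((3, 3)), np.full((3, 3), 40.0)])
    lay = ElectrodeLayout(tuple(f"e{i}" for i in range(6)), pos,
                          {"A": (0.0, 0.0, 0.0), "B": (40.0, 40.0, 40.0)})
    return assign_rois(projection_matrix(lay, 10.0), 0.1, 3)


class TestEvaluateFeature:
    def test_planted_effect_beats_chance(self, feature_rng):
        table = make_feature_table(140, 6, feature_rng,
                                   effect_channels=(0, 1, 2),
                                   effect_size=1.0)
        scheme = make_folds(140, 7, 1)
        out = evaluate_feature(table, _two_roi_assignment(), "A", "alpha",
                               scheme, ("Talking", "WatchingTV"), seed=0)
        assert np.mean([o.accuracy for o in out]) > 0.8

    def test_null_feature_near_chance(self, feature_rng):
        accs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            table = make_feature_table(140, 6, rng)
            scheme = make_folds(140, 7, 1)
            out = evaluate_feature(table, _two_roi_assignment(), "B", "beta",
                                   scheme, ("Talking", "WatchingTV"),
                                   seed=seed)
            accs.extend(o.accuracy for o in out)
        assert abs(np.mean(accs) - 0.5) < 0.06

    def test_sign_recovery_of_positive_effect(self, feature_rng):
        table = make_feature_table(140, 6, feature_rng,
                                   effect_channels=(0, 1, 2),
                                   effect_size=1.0)
        scheme = make_folds(140, 7, 1)
        out = evaluate_feature(table, _two_roi_assignment(), "A", "alpha",
                               scheme, ("Talking", "WatchingTV"), seed=0)
        signs = [o.mean_diff_scalar > 0 for o in out]
        assert np.mean(signs) >= 0.9


class TestEvaluateMulticlass:
    def _three_state_table(self, rng, separable):
        n_bins = 144
        labels = np.array(
            [("Talking", "WatchingTV", "UsingElectronics")[(b // 8) % 3]
             for b in range(n_bins)], dtype=object)
        table = make_feature_table(n_bins, 6, rng, labels=labels)
        if separable:
            for i, state in enumerate(("Talking", "WatchingTV",
                                       "UsingElectronics")):
                table.values[labels == state, :, i] += 1.5
        return table

    def test_separable_states_beat_third_chance(self, feature_rng):
        table = self._three_state_table(feature_rng, separable=True)
        scheme = make_folds(table.n_bins, 7, 1)
        out = evaluate_multiclass(table, _two_roi_assignment(),
                                  DEFAULT_BANDS, scheme,
                                  ("Talking", "WatchingTV",
                                   "UsingElectronics"), seed=0)
        accs = [o.accuracy for o in out["theta"]]
        assert np.mean(accs) > 0.6

    def test_shuffled_labels_near_third(self, feature_rng):
        table = self._three_state_table(feature_rng, separable=True)
        rng = np.random.default_rng(99)
        table.labels = rng.permutation(table.labels)
        scheme = make_folds(table.n_bins, 7, 1)
        out = evaluate_multiclass(table, _two_roi_assignment(),
                                  DEFAULT_BANDS, scheme,
                                  ("Talking", "WatchingTV",
                                   "UsingElectronics"), seed=0)
        accs = [o.accuracy for band in out.values() for o in band]
        assert abs(np.mean(accs) - 1 / 3) < 0.08

    def test_two_class_input_falls_back(self, feature_rng):
        table = make_feature_table(140, 6, feature_rng,
                                   effect_channels=(0, 1, 2),
                                   effect_size=1.0)
        scheme = make_folds(140, 7, 1)
        out = evaluate_multiclass(table, _two_roi_assignment(),
                                  ["alpha"], scheme,
                                  ("Talking", "WatchingTV"), seed=0)
        assert np.mean([o.accuracy for o in out["alpha"]]) > 0.8


class TestIncrementalRoiCurve:
    def test_single_informative_roi_ranked_first(self, feature_rng):
        table = make_feature_table(140, 6, feature_rng,
                                   effect_channels=(0, 1, 2),
                                   effect_size=1.0)
        scheme = make_folds(140, 7, 1)
        curve = incremental_roi_curve(table, _two_roi_assignment(), "alpha",
                                      scheme, ("Talking", "WatchingTV"),
                                      seed=0)
        assert [m for m, _ in curve] == [1, 2]
        # the informative ROI alone already performs well
        assert curve[0][1] > 0.8

    def test_single_retained_roi_gives_length_one(self, feature_rng):
        table = make_feature_table(140, 3, feature_rng,
                                   effect_channels=(0,), effect_size=1.0)
        pos = np.zeros((3, 3))
        lay = ElectrodeLayout(("a", "b", "c"), pos, {"A": (0.0, 0.0, 0.0)})
        assignment = assign_rois(projection_matrix(lay, 10.0), 0.1, 3)
        scheme = make_folds(140, 7, 1)
        curve = incremental_roi_curve(table, assignment, "alpha", scheme,
                                      ("Talking", "WatchingTV"), seed=0)
        assert len(curve) == 1

    def test_too_few_folds_rejected(self, feature_rng):
        table = make_feature_table(140, 6, feature_rng)
        scheme = make_folds(140, 2, 0)
        with pytest.raises(ValueError):
            incremental_roi_curve(table, _two_roi_assignment(), "alpha",
                                  scheme, ("Talking", "WatchingTV"), seed=0)
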