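import numpy as np
import pytest

import fcbands as fc
from fcbands.discrimination import (UnsupportedConfigurationError,
                                    _elimination_order, accuracy_curve,
                                    convergence_point, default_k_schedule,
                                    fit_svm, linear_weights, loocv_accuracy,
                                    loocv_predictions, nested_subsets,
                                    permutation_control, rfe_rank)
from conftest import make_feature_dataset


class TestFitSvm:
    def test_separable_one_dimensional_data_trains_perfectly(self, linear_spec):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(-1, 0.1, 20), rng.normal(1, 0.1, 20)])
        y = np.array([-1] * 20 + [1] * 20)
        model = fit_svm(x, y, linear_spec)
        assert (model.predict(x[:, None]) == y).mean() == 1.0

    def test_duplicated_feature_columns_share_weight(self, linear_spec):
        rng = np.random.default_rng(1)
        base = rng.standard_normal(30)
        y = np.sign(base + 0.1 * rng.standard_normal(30)).astype(int)
        y[y == 0] = 1
        X = np.column_stack([base, base, rng.standard_normal(30)])
        w = linear_weights(fit_svm(X, y, linear_spec))
        assert abs(w[0] - w[1]) < 1e-6

    def test_label_flip_negates_decision_function(self, linear_spec):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((20, 3))
        y = np.array([1, -1] * 10)
        d1 = fit_svm(X, y, linear_spec).decision_function(X)
        d2 = fit_svm(X, -y, linear_spec).decision_function(X)
        # symmetry holds up to the dual solver's convergence tolerance
        assert np.allclose(d1, -d2, atol=1e-2)
        assert np.array_equal(np.sign(d1), -np.sign(d2))

    def test_single_class_and_nonfinite_rejected(self, linear_spec):
        X = np.zeros((4, 2))
        with pytest.raises(ValueError, match="classes"):
            fit_svm(X, np.ones(4), linear_spec)
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            fit_svm(X, np.array([1, 1, -1, -1]), linear_spec)

    def test_rbf_kernel_has_no_feature_weights(self):
        spec = fc.ClassifierSpec(kernel="rbf")
        rng = np.random.default_rng(3)
        model = fit_svm(rng.standard_normal((10, 2)),
                        np.array([1, -1] * 5), spec)
        with pytest.raises(UnsupportedConfigurationError):
            linear_weights(model)


class TestRfeRank:
    def test_informative_features_rank_top_two_matching_loocv_oracle(
            self, linear_spec):
        # 2 informative features (group shift d ~ 2) + 8 noise, K = 40
        rng = np.random.default_rng(42)
        y = np.array([1] * 20 + [-1] * 20)
        X = rng.standard_normal((40, 10))
        X[:, 3] += y * 1.0   # d = 2 with unit noise
        X[:, 7] += y * 1.0
        ds = make_feature_dataset(X, y)
        ranking = rfe_rank(ds, linear_spec, step=1)
        assert set(ranking.order[:2]) == {3, 7}
        # independent oracle: exhaustive single-feature LOOCV ordering
        single = [loocv_accuracy(ds, [f], linear_spec) for f in range(10)]
        assert set(np.argsort(single)[-2:]) == {3, 7}

    def test_single_feature_trivial_ranking(self, linear_spec):
        ds = make_feature_dataset(np.array([[0.], [1.], [2.], [3.]]),
                                  np.array([1, 1, -1, -1]))
        assert rfe_rank(ds, linear_spec, step=1).order == (0,)

    def test_ranking_is_bitwise_stable(self, linear_spec):
        rng = np.random.default_rng(5)
        ds = make_feature_dataset(rng.standard_normal((20, 30)),
                                  np.array([1, -1] * 10))
        r1 = rfe_rank(ds, linear_spec, step=1)
        r2 = rfe_rank(ds, linear_spec, step=1)
        assert r1.order == r2.order

    def test_matches_sklearn_rfe_cross_check(self, linear_spec):
        # independent implementation of the same elimination criterion
        from sklearn.feature_selection import RFE
        from sklearn.svm import SVC
        rng = np.random.default_rng(6)
        y = np.array([1] * 10 + [-1] * 10)
        X = rng.standard_normal((20, 12))
        X[:, 2] += y * 0.8
        ds = make_feature_dataset(X, y)
        mine = rfe_rank(ds, linear_spec, step=1)
        ref = RFE(SVC(kernel="linear", C=1.0), n_features_to_select=1,
                  step=1).fit(X, y)
        my_positions = 1 + np.array([mine.order.index(f) for f in range(12)])
        assert np.array_equal(my_positions, ref.ranking_)

    def test_chunked_schedule_is_valid_permutation(self, linear_spec):
        rng = np.random.default_rng(7)
        ds = make_feature_dataset(rng.standard_normal((20, 300)),
                                  np.array([1, -1] * 10))
        ranking = rfe_rank(ds, linear_spec, step=0.1, chunk_until=50)
        assert sorted(ranking.order) == list(range(300))

    def test_tie_break_eliminates_larger_index_first(self):
        crit = np.array([0.5, 0.1, 0.1, 0.9])
        surviving = np.array([10, 11, 12, 13])
        drop = _elimination_order(crit, surviving, 2)
        # both ties at 0.1; larger feature index (12) goes first
        assert list(surviving[drop]) == [12, 11]

    def test_rbf_kernel_refused_for_ranking(self):
        ds = make_feature_dataset(np.random.default_rng(8).standard_normal((8, 3)),
                                  np.array([1, -1] * 4))
        with pytest.raises(UnsupportedConfigurationError):
            rfe_rank(ds, fc.ClassifierSpec(kernel="rbf"), step=1)


class TestNestedSubsets:
    def test_top_k_of_explicit_ranking(self):
        ranking = fc.FeatureRanking(order=(2, 0, 1))
        assert nested_subsets(ranking, [2]) == [(2, 0)]

    def test_subsets_are_nested(self):
        ranking = fc.FeatureRanking(order=tuple(np.random.default_rng(9)
                                                .permutation(15)))
        subsets = nested_subsets(ranking, list(range(1, 16)))
        for a, b in zip(subsets, subsets[1:]):
            assert set(a) < set(b)
        assert set(subsets[-1]) == set(range(15))

    def test_k_beyond_feature_count_rejected(self):
        with pytest.raises(ValueError):
            nested_subsets(fc.FeatureRanking(order=(0, 1)), [3])


class TestLoocv:
    def test_one_fold_per_subject(self, small_planted_cohort, linear_spec):
        subjects, labels, _ = small_planted_cohort
        ds = fc.build_dataset([fc.condition(ts, fc.SLOW5) for ts in subjects],
                              labels, band="slow5")
        preds = loocv_predictions(ds.X[:, :5], ds.y, linear_spec)
        assert preds.shape == (39,)

    def test_perfectly_separated_groups_reach_accuracy_one(
            self, small_planted_cohort, linear_spec):
        subjects, labels, truth = small_planted_cohort
        ds = fc.build_dataset([fc.condition(ts, fc.SLOW5) for ts in subjects],
                              labels, band="slow5")
        acc = loocv_accuracy(ds, truth.edge_feature_indices, linear_spec)
        assert acc == 1.0

    def test_null_accuracy_not_optimistically_biased(self, linear_spec):
        # under the null, LOOCV must not exceed majority-class chance;
        # with 19/20 imbalance it is in fact pessimistically biased
        accs = []
        for rep in range(30):
            rng = np.random.default_rng(600 + rep)
            ds = make_feature_dataset(rng.standard_normal((39, 45)),
                                      np.array([1] * 19 + [-1] * 20))
            accs.append(loocv_accuracy(ds, range(45), linear_spec))
        accs = np.asarray(accs)
        chance = 20 / 39
        se = accs.std(ddof=1) / np.sqrt(len(accs))
        assert accs.mean() <= chance + 3 * se
        assert accs.mean() > chance - 0.1

    def test_singleton_class_training_fold_rejected(self, linear_spec):
        X = np.random.default_rng(10).standard_normal((5, 2))
        y = np.array([1, -1, -1, -1, -1])
        with pytest.raises(ValueError, match="single class"):
            loocv_predictions(X, y, linear_spec)

    def test_too_few_subjects_rejected(self, linear_spec):
        with pytest.raises(ValueError, match="K >= 4"):
            loocv_predictions(np.zeros((3, 2)), np.array([1, -1, 1]),
                              linear_spec)


class TestAccuracyCurve:
    def test_single_point_schedule_equals_all_feature_loocv(self, linear_spec):
        rng = np.random.default_rng(11)
        y = np.array([1] * 10 + [-1] * 10)
        X = rng.standard_normal((20, 6)) + y[:, None] * 0.5
        ds = make_feature_dataset(X, y)
        ranking = rfe_rank(ds, linear_spec, step=1)
        curve = accuracy_curve(ds, linear_spec, k_schedule=[6],
                               ranking=ranking)
        assert curve.accuracy[0] == loocv_accuracy(ds, range(6), linear_spec)

    def test_values_bounded_and_mode_recorded(self, linear_spec):
        rng = np.random.default_rng(12)
        y = np.array([1] * 8 + [-1] * 8)
        ds = make_feature_dataset(rng.standard_normal((16, 10)), y)
        curve = accuracy_curve(ds, linear_spec, k_schedule=[1, 3, 5],
                               mode="nested", rfe_step=1)
        assert all(0.0 <= a <= 1.0 for a in curve.accuracy)
        assert curve.mode == "nested"
        assert len(curve.k_values) == 3

    def test_strong_planted_effect_converges_to_one(self, linear_spec,
                                                    small_planted_cohort):
        subjects, labels, _ = small_planted_cohort
        ds = fc.build_dataset([fc.condition(ts, fc.SLOW5) for ts in subjects],
                              labels, band="slow5")
        curve = accuracy_curve(ds, linear_spec,
                               k_schedule=list(range(1, 21)), rfe_step=1,
                               convergence_window=5)
        assert max(curve.accuracy) == 1.0
        assert curve.convergence_k is not None and curve.convergence_k <= 20
        assert curve.converged_accuracy >= curve.accuracy[0]


class TestConvergencePoint:
    def curve(self, accs, window=None):
        return fc.AccuracyCurve(band="b", k_values=tuple(range(1, len(accs) + 1)),
                                accuracy=tuple(accs))

    def test_plateau_detected_at_first_maximal_k(self):
        k, a = convergence_point(self.curve([0.5, 0.8, 1.0, 1.0, 1.0]), window=2)
        assert (k, a) == (3, 1.0)

    def test_constant_curve_converges_immediately(self):
        k, a = convergence_point(self.curve([0.9] * 5), window=2)
        assert (k, a) == (1, 0.9)

    def test_early_touch_with_dip_is_skipped(self):
        accs = [0.6, 1.0, 0.7, 1.0, 1.0, 1.0, 1.0]
        k, a = convergence_point(self.curve(accs), window=2)
        assert (k, a) == (4, 1.0)

    def test_window_larger_than_curve_falls_back_to_held_to_end(self):
        k, a = convergence_point(self.curve([0.5, 1.0, 1.0]), window=10)
        assert (k, a) == (2, 1.0)

    def test_no_sustained_plateau_returns_none(self):
        k, a = convergence_point(self.curve([0.5, 1.0, 0.4, 0.5, 0.45]),
                                 window=2)
        assert k is None and a is None

    def test_tolerance_allows_small_dips(self):
        accs = [0.5, 1.0, 0.95, 1.0, 1.0]
        k, _ = convergence_point(self.curve(accs), window=3, tolerance=0.05)
        assert k == 2


class TestPermutationControl:
    def test_seeded_determinism(self, linear_spec):
        rng = np.random.default_rng(13)
        ds = make_feature_dataset(rng.standard_normal((12, 5)),
                                  np.array([1, -1] * 6))
        a = permutation_control(ds, linear_spec, 3, rng=99)
        b = permutation_control(ds, linear_spec, 3, rng=99)
        assert a.permuted_accuracies == b.permuted_accuracies

    def test_empirical_p_floor_when_observed_beats_all(self, linear_spec):
        rng = np.random.default_rng(14)
        ds = make_feature_dataset(rng.standard_normal((12, 5)),
                                  np.array([1, -1] * 6))
        res = permutation_control(ds, linear_spec, 9, rng=1,
                                  observed_accuracy=1.01)
        assert res.empirical_p == 1 / 10

    def test_chance_level_is_majority_class_proportion(self, linear_spec):
        rng = np.random.default_rng(15)
        ds = make_feature_dataset(rng.standard_normal((39, 4)),
                                  np.array([1] * 19 + [-1] * 20))
        res = permutation_control(ds, linear_spec, 1, rng=0)
        assert np.isclose(res.chance_level, 20 / 39)

    def test_strong_effect_unpermuted_beats_permuted(self, linear_spec,
                                                     small_planted_cohort):
        subjects, labels, truth = small_planted_cohort
        ds = fc.build_dataset([fc.condition(ts, fc.SLOW5) for ts in subjects],
                              labels, band="slow5")
        sel = truth.edge_feature_indices
        observed = loocv_accuracy(ds, sel, linear_spec)
        res = permutation_control(ds, linear_spec, 10, rng=3,
                                  selected_features=sel,
                                  observed_accuracy=observed)
        assert observed == 1.0
        assert max(res.permuted_accuracies) < observed
        assert res.empirical_p == 1 / 11


class TestDefaultSchedule:
    def test_dense_then_geometric_reaches_full_feature_count(self):
        ks = default_k_schedule(4005)
        assert ks[:200] == list(range(1, 201))
        assert ks[-1] == 4005
        assert ks == sorted(set(ks))

    def test_small_p_is_fully_dense(self):
        assert default_k_schedule(45) == list(range(1, 46))
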