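"""Nearest shrunken centroids: hand values, oracles, CV and threshold selection."""

import numpy as np
import pandas as pd
import pytest

from renalclass import (
    NearestShrunkenCentroids,
    evaluate_predictions,
    nsc_cross_validate,
    nsc_predict,
    nsc_select_threshold,
    nsc_train,
)
from renalclass.nsc import CvCurve


def _fit(X, y, **kw):
    return NearestShrunkenCentroids(**kw).fit(np.asarray(X, float), np.asarray(y))


class TestFitHandValues:
    """One feature, classes {0, 2} vs {4, 6}: every quantity by hand."""

    @pytest.fixture()
    def model(self):
        return _fit([[0.0], [2.0], [4.0], [6.0]], list("aabb"), s0=0.0)

    def test_centroids_and_pooled_sd(self, model):
        np.testing.assert_allclose(model.centroids_, [[1.0, 5.0]])
        np.testing.assert_allclose(model.overall_centroid_, [3.0])
        # ss = 1+1+1+1 over n-K = 2 -> s = sqrt(2)
        np.testing.assert_allclose(model.s_, [np.sqrt(2.0)])
        np.testing.assert_allclose(model.m_, [0.5, 0.5])

    def test_raw_scores(self, model):
        # d = (1 - 3) / (0.5 * sqrt(2)) = -2 sqrt(2)
        np.testing.assert_allclose(model.scores_, [[-2 * np.sqrt(2), 2 * np.sqrt(2)]])
        assert model.max_score_ == pytest.approx(2.8284, abs=1e-4)

    def test_soft_threshold_at_one(self, model):
        got = model.shrunken_scores(1.0)
        np.testing.assert_allclose(got, [[-1.8284, 1.8284]], atol=1e-4)

    def test_shrunken_centroids_move_toward_overall(self, model):
        cent = model.shrunken_centroids(1.0)
        # overall + m * s * d' = 3 +/- 0.5 * sqrt(2) * 1.8284...
        shift = 0.5 * np.sqrt(2.0) * (2 * np.sqrt(2) - 1.0)
        np.testing.assert_allclose(cent, [[3.0 - shift, 3.0 + shift]])

    def test_full_shrinkage_collapses_to_overall(self, model):
        cent = model.shrunken_centroids(model.max_score_ + 1.0)
        np.testing.assert_allclose(cent, [[3.0, 3.0]])


class TestScoresStructure:
    def test_two_class_scores_exactly_antisymmetric(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(14, 300))
        y = np.array(["a"] * 7 + ["b"] * 7)
        model = _fit(X, y)
        np.testing.assert_array_equal(model.scores_[:, 0], -model.scores_[:, 1])

    def test_unbalanced_classes_antisymmetric_to_rounding(self):
        # with n1 != n2 the class standardizers m_k differ, so antisymmetry
        # holds algebraically but not bitwise
        rng = np.random.default_rng(1)
        X = rng.normal(size=(13, 50))
        y = np.array(["a"] * 5 + ["b"] * 8)
        model = _fit(X, y)
        np.testing.assert_allclose(model.scores_[:, 0], -model.scores_[:, 1], rtol=1e-12)

    def test_survivor_counts_non_increasing_to_zero(self):
        rng = np.random.default_rng(2)
        model = _fit(rng.normal(size=(12, 80)), ["a"] * 6 + ["b"] * 6)
        counts = model.survivor_counts()
        assert counts[0] == 80
        assert counts[-1] <= 2  # only the max-|d| feature can survive the top grid point
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_s0_is_requested_percentile(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 40))
        y = ["a"] * 5 + ["b"] * 5
        model = _fit(X, y, s0_percentile=30.0)
        assert model.s0_ == pytest.approx(np.percentile(model.s_, 30.0))
        assert _fit(X, y, s0=0.123).s0_ == 0.123

    def test_three_class_scores_match_definition(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(15, 20))
        y = np.repeat(["a", "b", "c"], 5)
        model = _fit(X, y)
        expected = (model.centroids_ - model.overall_centroid_[:, None]) / (
            model.m_[None, :] * (model.s_ + model.s0_)[:, None]
        )
        np.testing.assert_allclose(model.scores_, expected, rtol=1e-10)


class TestValidation:
    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            _fit(np.ones((4, 2)), ["a"] * 4)

    def test_singleton_class_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            _fit(np.ones((3, 2)), ["a", "a", "b"])

    def test_non_finite_rejected(self):
        X = np.ones((4, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            _fit(X, ["a", "a", "b", "b"])

    def test_bad_m_form_rejected(self):
        with pytest.raises(ValueError, match="m_form"):
            _fit(np.eye(4), ["a", "a", "b", "b"], m_form="divide")

    def test_bad_priors_rejected(self):
        with pytest.raises(ValueError, match="priors"):
            _fit(np.eye(4), ["a", "a", "b", "b"], priors=[0.9, 0.9])

    def test_feature_mismatch_at_predict(self):
        model = _fit(np.eye(4), ["a", "a", "b", "b"])
        with pytest.raises(ValueError, match="features"):
            model.predict(np.ones((1, 5)))


def brute_force_discriminant(model, X, shrinkage):
    """Loop form of delta_k(x) over surviving features."""
    cent = model.shrunken_centroids(shrinkage)
    surv = model.survivors(shrinkage)
    out = np.zeros((X.shape[0], model.classes_.size))
    for i, x in enumerate(X):
        for k in range(model.classes_.size):
            total = 0.0
            for j in np.flatnonzero(surv):
                total += (x[j] - cent[j, k]) ** 2 / (model.s_[j] + model.s0_) ** 2
            out[i, k] = total - 2.0 * np.log(model.priors_[k])
    return out


class TestPrediction:
    def test_discriminant_matches_brute_force(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(10, 15))
        y = ["a"] * 5 + ["b"] * 5
        model = _fit(X, y)
        Xnew = rng.normal(size=(4, 15))
        for delta in (0.0, 0.5 * model.max_score_):
            np.testing.assert_allclose(
                model.decision_function(Xnew, delta),
                brute_force_discriminant(model, Xnew, delta),
                rtol=1e-10,
            )

    def test_class_centroid_classified_to_its_class(self):
        rng = np.random.default_rng(6)
        X = np.vstack([rng.normal(0, 1, (6, 30)), rng.normal(2, 1, (6, 30))])
        y = ["a"] * 6 + ["b"] * 6
        model = _fit(X, y)
        pred = model.predict(model.centroids_.T)
        np.testing.assert_array_equal(pred, model.classes_)

    def test_full_shrinkage_predicts_larger_prior(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(10, 8))
        y = ["a"] * 3 + ["b"] * 7
        model = _fit(X, y)
        pred = model.predict(rng.normal(size=(5, 8)), shrinkage=model.max_score_ + 1)
        assert set(pred) == {"b"}

    def test_separated_training_data_refit_perfectly(self):
        rng = np.random.default_rng(8)
        X = np.vstack([rng.normal(-3, 0.5, (8, 20)), rng.normal(3, 0.5, (8, 20))])
        y = np.array(["a"] * 8 + ["b"] * 8)
        model = _fit(X, y)
        np.testing.assert_array_equal(model.predict(X), y)


class TestMatrixWrappers:
    def test_train_records_probe_ids(self, small_matrix):
        model = nsc_train(small_matrix)
        assert model.probe_ids_ == list(small_matrix.probe_ids)
        assert model.n_features_in_ == small_matrix.n_probes

    def test_predict_single_sample(self, small_matrix):
        model = nsc_train(small_matrix)
        x = small_matrix.values.iloc[:, 0].to_numpy()
        cls, scores = nsc_predict(model, 0.0, x)
        assert cls in model.classes_
        assert scores.shape == (2,)
        assert cls == model.classes_[np.argmin(scores)]

    def test_missing_labels_rejected(self, small_matrix):
        from renalclass import ExpressionMatrix

        bare = ExpressionMatrix(small_matrix.values)
        with pytest.raises(ValueError, match="labels"):
            nsc_train(bare)


@pytest.fixture(scope="module")
def separated():
    rng = np.random.default_rng(9)
    X = np.vstack([rng.normal(0, 1, (15, 100)), rng.normal(0, 1, (15, 100))])
    X[:15, :5] += 4.0  # five informative features
    y = np.array(["a"] * 15 + ["b"] * 15)
    return X, y


class TestCrossValidation:

    def test_deterministic_given_seed(self, separated):
        X, y = separated
        c1 = nsc_cross_validate(X, y, seed=3)
        c2 = nsc_cross_validate(X, y, seed=3)
        np.testing.assert_array_equal(c1.errors, c2.errors)
        np.testing.assert_array_equal(c1.mean_survivors, c2.mean_survivors)
        assert c1.fold_assignment.equals(c2.fold_assignment)

    def test_separated_classes_reach_zero_error(self, separated):
        X, y = separated
        curve = nsc_cross_validate(X, y, seed=0)
        assert curve.errors.min() == 0.0

    def test_permuted_labels_error_near_half(self, separated):
        X, y = separated
        rng = np.random.default_rng(10)
        curve = nsc_cross_validate(X, rng.permutation(y), seed=0)
        # chance-level classification across most of the grid
        assert abs(np.median(curve.errors) - 0.5) < 0.2

    def test_fold_reduction_warns(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(8, 10))
        y = np.array(["a"] * 4 + ["b"] * 4)
        with pytest.warns(UserWarning, match="reducing folds"):
            curve = nsc_cross_validate(X, y, n_folds=10, seed=0)
        assert curve.n_folds == 4

    def test_stratified_fold_assignment_covers_all(self, separated):
        X, y = separated
        curve = nsc_cross_validate(X, y, n_folds=5, seed=0)
        assert sorted(curve.fold_assignment.unique()) == [0, 1, 2, 3, 4]
        for f in range(5):
            members = y[curve.fold_assignment.to_numpy() == f]
            assert set(members) == {"a", "b"}


def _curve(errors, survivors, thresholds=None):
    errors = np.asarray(errors, float)
    if thresholds is None:
        thresholds = np.arange(1.0, errors.size + 1)
    return CvCurve(
        thresholds=np.asarray(thresholds, float),
        errors=errors,
        mean_survivors=np.asarray(survivors, float),
        fold_assignment=pd.Series(dtype=int),
        seed=0,
        n_folds=10,
    )


class TestSelectThreshold:
    def test_smallest_qualifying_predictor_wins(self):
        curve = _curve([0.20, 0.08, 0.05, 0.12], [500, 40, 14, 6])
        threshold, size = nsc_select_threshold(curve, max_error=0.10)
        assert (threshold, size) == (3.0, 14.0)

    def test_no_qualifier_raises_with_minimum(self):
        curve = _curve([0.3, 0.25, 0.2], [50, 20, 5])
        with pytest.raises(ValueError, match="0.2"):
            nsc_select_threshold(curve, max_error=0.10)

    def test_tie_on_size_goes_to_larger_threshold(self):
        curve = _curve([0.05, 0.05, 0.05], [14, 14, 20])
        threshold, size = nsc_select_threshold(curve)
        assert (threshold, size) == (2.0, 14.0)

    def test_empty_curve_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            nsc_select_threshold(_curve([], []))


class TestEvaluatePredictions:
    def test_28_of_30_is_93_percent(self):
        y_true = ["a"] * 15 + ["b"] * 15
        y_pred = list(y_true)
        y_pred[0], y_pred[16] = "b", "a"
        res = evaluate_predictions(y_true, y_pred)
        assert (res.n_correct, res.n_total) == (28, 30)
        assert round(100 * res.accuracy) == 93

    def test_17_of_18_is_94_percent(self):
        y_true = ["a"] * 9 + ["b"] * 9
        y_pred = list(y_true)
        y_pred[3] = "b"
        res = evaluate_predictions(y_true, y_pred)
        assert (res.n_correct, res.n_total) == (17, 18)
        assert round(100 * res.accuracy) == 94

    def test_confusion_table_layout(self):
        res = evaluate_predictions(["a", "a", "b"], ["a", "b", "b"])
        assert res.table.loc["a", "b"] == 1
        assert res.table.loc["a", "a"] == 1
        assert res.table.loc["b", "b"] == 1

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            evaluate_predictions(["a", "b"], ["a", "c"], classes=["a", "b"])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            evaluate_predictions(["a"], ["a", "b"])
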