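"""Nearest shrunken centroids (PAM) with cross-validated threshold selection.

The estimator soft-thresholds standardized class-centroid deviations

    d_ik = (xbar_ik - xbar_i) / (m_k (s_i + s0)),   m_k = sqrt(1/n_k - 1/n)

where s_i is the pooled within-class standard deviation and s0 a percentile
of {s_i} (the "offset percentage", default 30). Shrinking |d_ik| by a
threshold Delta zeroes uninformative genes, yielding a sparse predictor.
Classification minimizes the discriminant

    delta_k(x) = sum_surviving (x_i - xbar'_ik)^2 / (s_i + s0)^2 - 2 log pi_k.

Model selection follows an explicit rule: 10-fold cross-validation over a
100-point threshold grid, then the smallest predictor whose cross-validated
misclassification error is at most 10%.

:class:`NearestShrunkenCentroids` is a scikit-learn estimator (rows are
samples); the ``nsc_*`` functions wrap it for probes-x-samples expression
matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .io import ExpressionMatrix

__all__ = [
    "NearestShrunkenCentroids",
    "CvCurve",
    "ConfusionResult",
    "nsc_train",
    "nsc_predict",
    "nsc_cross_validate",
    "nsc_select_threshold",
    "evaluate_predictions",
]


class NearestShrunkenCentroids(ClassifierMixin, BaseEstimator):
    """Nearest-shrunken-centroid classifier.

    Parameters
    ----------
    shrinkage : float, default 0.0
        Soft threshold Delta applied to the standardized centroid scores.
    s0_percentile : float, default 30.0
        Percentile of the per-feature pooled standard deviations used as
        the variance-stabilizing offset s0.
    s0 : float or None, default None
        Explicit offset overriding ``s0_percentile`` when given.
    n_thresholds : int, default 100
        Size of the linear threshold grid on [0, max |d_ik|] stored at fit
        time (both endpoints included).
    priors : 'empirical' or array-like, default 'empirical'
        Class priors pi_k; 'empirical' uses class frequencies.
    m_form : {'subtract', 'sum'}, default 'subtract'
        Form of the standardizer m_k: sqrt(1/n_k - 1/n) (variance-correct)
        or sqrt(1/n_k + 1/n).

    Attributes (after ``fit``)
    ----------
    classes_, centroids_ (p, K), overall_centroid_ (p,), s_ (p,), s0_,
    m_ (K,), priors_ (K,), scores_ (p, K) raw d_ik, threshold_grid_ (G,).
    """

    def __init__(self, shrinkage: float = 0.0, s0_percentile: float = 30.0,
                 n_thresholds: int = 100, priors="empirical", m_form: str = "subtract",
                 s0: float | None = None):
        self.shrinkage = shrinkage
        self.s0_percentile = s0_percentile
        self.n_thresholds = n_thresholds
        self.priors = priors
        self.m_form = m_form
        self.s0 = s0

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n_samples, n_features) aligned with y")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        if self.m_form not in ("subtract", "sum"):
            raise ValueError("m_form must be 'subtract' or 'sum'")
        classes, y_idx = np.unique(y, return_inverse=True)
        counts = np.bincount(y_idx)
        if classes.size < 2:
            raise ValueError("at least two classes required")
        if counts.min() < 2:
            raise ValueError("every class needs at least 2 samples")
        n, p = X.shape
        K = classes.size

        centroids = np.stack([X[y_idx == k].mean(axis=0) for k in range(K)], axis=1)  # p x K
        ss = np.zeros(p)
        for k in range(K):
            ss += ((X[y_idx == k] - centroids[:, k]) ** 2).sum(axis=0)
        s = np.sqrt(ss / (n - K))
        s0 = float(np.percentile(s, self.s0_percentile)) if self.s0 is None else float(self.s0)
        if self.m_form == "subtract":
            m = np.sqrt(1.0 / counts - 1.0 / n)
        else:
            m = np.sqrt(1.0 / counts + 1.0 / n)
        overall = (centroids * (counts / n)).sum(axis=1)

        if K == 2:
            # pairwise form: numerator_k = +/- (n_other/n) * (xbar_1 - xbar_2).
            # Algebraically identical to xbar_k - xbar, but exact in floating
            # point: with balanced classes d_i1 == -d_i2 bitwise.
            delta12 = centroids[:, 0] - centroids[:, 1]
            deviation = np.stack(
                [(counts[1] / n) * delta12, -((counts[0] / n) * delta12)], axis=1
            )
        else:
            deviation = centroids - overall[:, None]
        scores = deviation / (m[None, :] * (s + s0)[:, None])

        if isinstance(self.priors, str) and self.priors == "empirical":
            priors = counts / n
        else:
            priors = np.asarray(self.priors, dtype=float)
            if priors.shape != (K,) or not np.isclose(priors.sum(), 1.0):
                raise ValueError("priors must be K probabilities summing to 1")

        self.classes_ = classes
        self.class_counts_ = counts
        self.centroids_ = centroids
        self.overall_centroid_ = overall
        self.s_ = s
        self.s0_ = s0
        self.m_ = m
        self.priors_ = priors
        self.scores_ = scores
        self.max_score_ = float(np.abs(scores).max())
        self.threshold_grid_ = np.linspace(0.0, self.max_score_, self.n_thresholds)
        self.n_features_in_ = p
        return self

    # -- shrinkage machinery -------------------------------------------------

    def shrunken_scores(self, shrinkage: float | None = None) -> np.ndarray:
        """Soft-thresholded scores d'_ik = sign(d) max(|d| - Delta, 0)."""
        check_is_fitted(self, "scores_")
        delta = self.shrinkage if shrinkage is None else shrinkage
        return np.sign(self.scores_) * np.maximum(np.abs(self.scores_) - delta, 0.0)

    def survivors(self, shrinkage: float | None = None) -> np.ndarray:
        """Boolean mask of features with a nonzero shrunken score in any class."""
        return np.any(self.shrunken_scores(shrinkage) != 0.0, axis=1)

    def n_survivors(self, shrinkage: float | None = None) -> int:
        return int(self.survivors(shrinkage).sum())

    def survivor_counts(self) -> np.ndarray:
        """Surviving-feature count at every grid threshold (non-increasing)."""
        check_is_fitted(self, "scores_")
        return np.array([self.n_survivors(t) for t in self.threshold_grid_])

    def shrunken_centroids(self, shrinkage: float | None = None) -> np.ndarray:
        dprime = self.shrunken_scores(shrinkage)
        return self.overall_centroid_[:, None] + self.m_[None, :] * (
            (self.s_ + self.s0_)[:, None] * dprime
        )

    # -- prediction ----------------------------------------------------------

    def decision_function(self, X, shrinkage: float | None = None) -> np.ndarray:
        """Discriminant delta_k per sample (smaller is better); (n, K)."""
        check_is_fitted(self, "scores_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, model was fitted with {self.n_features_in_}"
            )
        surv = self.survivors(shrinkage)
        cent = self.shrunken_centroids(shrinkage)[surv]  # p' x K
        denom = (self.s_ + self.s0_)[surv]
        Xs = X[:, surv]
        diff = Xs[:, :, None] - cent[None, :, :]
        dist = (diff**2 / denom[None, :, None] ** 2).sum(axis=1)
        return dist - 2.0 * np.log(self.priors_)[None, :]

    def predict(self, X, shrinkage: float | None = None):
        scores = self.decision_function(X, shrinkage)
        # argmin with ties broken toward the larger prior, then label order
        order = np.lexsort((np.arange(self.classes_.size), -self.priors_))
        best = order[np.argmin(scores[:, order], axis=1)]
        return self.classes_[best]


@dataclass
class CvCurve:
    """Cross-validated error and predictor size across the threshold grid."""

    thresholds: np.ndarray  # full-model grid values
    errors: np.ndarray  # CV misclassification error per grid point
    mean_survivors: np.ndarray  # mean surviving-feature count across folds
    fold_assignment: pd.Series  # fold index per sample
    seed: int
    n_folds: int


@dataclass
class ConfusionResult:
    table: pd.DataFrame  # true class x predicted class counts
    accuracy: float
    n_correct: int
    n_total: int


# ---------------------------------------------------------------------------
# Expression-matrix wrappers and the selection protocol
# ---------------------------------------------------------------------------


def _matrix_xy(matrix: ExpressionMatrix, labels=None):
    if labels is None:
        labels = matrix.labels
    if labels is None:
        raise ValueError("labels required")
    y = np.asarray(labels.loc[matrix.sample_ids] if isinstance(labels, pd.Series) else labels)
    return matrix.values.to_numpy().T, y


def nsc_train(matrix: ExpressionMatrix, labels=None, s0_percentile: float = 30.0,
              n_thresholds: int = 100) -> NearestShrunkenCentroids:
    X, y = _matrix_xy(matrix, labels)
    model = NearestShrunkenCentroids(s0_percentile=s0_percentile, n_thresholds=n_thresholds)
    model.fit(X, y)
    model.probe_ids_ = list(matrix.probe_ids)
    return model


def nsc_predict(model: NearestShrunkenCentroids, threshold: float, sample):
    """Classify one sample vector (aligned to the model's probes)."""
    x = np.asarray(sample, dtype=float).ravel()
    scores = model.decision_function(x[None, :], shrinkage=threshold)[0]
    cls = model.predict(x[None, :], shrinkage=threshold)[0]
    return cls, scores


def nsc_cross_validate(matrix_or_X, labels=None, n_folds: int = 10, n_thresholds: int = 100,
                       seed: int = 0, s0_percentile: float = 30.0) -> CvCurve:
    """Stratified k-fold CV over the shared grid of relative threshold positions.

    Each training split refits everything (s, s0, scores, grid); test samples
    are scored at the same relative quantile positions of the fold's own
    grid, so curves aggregate across folds. Reported thresholds are the
    full-model grid values.
    """
    if isinstance(matrix_or_X, ExpressionMatrix):
        X, y = _matrix_xy(matrix_or_X, labels)
        sample_ids = list(matrix_or_X.sample_ids)
    else:
        X = np.asarray(matrix_or_X, dtype=float)
        y = np.asarray(labels)
        sample_ids = list(range(X.shape[0]))
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        eff = int(counts.min())
        warnings.warn(
            f"smallest class has {eff} samples; reducing folds {n_folds} -> {eff}",
            stacklevel=2,
        )
        n_folds = eff
    if n_folds < 2:
        raise ValueError("cross-validation requires at least 2 usable folds")

    full = NearestShrunkenCentroids(s0_percentile=s0_percentile, n_thresholds=n_thresholds)
    full.fit(X, y)
    rel = np.linspace(0.0, 1.0, n_thresholds)

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    errors = np.zeros(n_thresholds)
    survivors = np.zeros(n_thresholds)
    fold_of = np.empty(len(y), dtype=int)
    for f, (tr, te) in enumerate(skf.split(X, y)):
        fold_of[te] = f
        if np.unique(y[tr]).size < classes.size:
            raise ValueError(f"fold {f} lost an entire class from the training split")
        model = NearestShrunkenCentroids(s0_percentile=s0_percentile, n_thresholds=n_thresholds)
        model.fit(X[tr], y[tr])
        grid = rel * model.max_score_
        for g, t in enumerate(grid):
            pred = model.predict(X[te], shrinkage=t)
            errors[g] += (pred != y[te]).sum()
            survivors[g] += model.n_survivors(t)
    errors /= len(y)
    survivors /= n_folds
    return CvCurve(
        thresholds=full.threshold_grid_.copy(),
        errors=errors,
        mean_survivors=survivors,
        fold_assignment=pd.Series(fold_of, index=sample_ids),
        seed=seed,
        n_folds=n_folds,
    )


def nsc_select_threshold(curve: CvCurve, max_error: float = 0.10) -> tuple[float, float]:
    """The minimal-predictor rule: among thresholds with CV error <= max_error,
    pick the one with the fewest surviving features; ties go to the largest
    threshold. Returns (threshold, expected surviving-feature count).
    """
    if curve.thresholds.size == 0:
        raise ValueError("empty CV curve")
    ok = np.flatnonzero(curve.errors <= max_error)
    if ok.size == 0:
        raise ValueError(
            f"no threshold reaches CV error <= {max_error:.3g} "
            f"(minimum achieved: {curve.errors.min():.3g})"
        )
    counts = curve.mean_survivors[ok]
    best_count = counts.min()
    candidates = ok[counts == best_count]
    idx = candidates[np.argmax(curve.thresholds[candidates])]
    return float(curve.thresholds[idx]), float(curve.mean_survivors[idx])


def evaluate_predictions(y_true, y_pred, classes=None) -> ConfusionResult:
    """Confusion matrix and overall accuracy."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    else:
        classes = np.asarray(classes)
        unknown = (set(y_true) | set(y_pred)) - set(classes)
        if unknown:
            raise ValueError(f"labels outside declared classes: {sorted(unknown)}")
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    table = pd.DataFrame(cm, index=classes, columns=classes)
    n_correct = int(np.trace(cm))
    n_total = int(cm.sum())
    return ConfusionResult(table, n_correct / n_total, n_correct, n_total)
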