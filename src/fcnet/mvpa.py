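"""Individual-level discrimination by maximum-uncertainty LDA (MLDA).

Features (edgewise connectivity and/or AUC metrics) are screened by
two-sample t-tests, classified with a linear discriminant whose pooled
within-class covariance is repaired by maximum-entropy eigenvalue
selection (eigenvalues below their mean are raised to the mean, so the
matrix is always invertible even when n < p), and evaluated by
leave-one-out cross-validation with permutation-based significance.
Feature selection is nested inside the cross-validation loop by default;
``whole_sample_selection`` uses whole-sample pre-selection instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted


def _as_matrix(features) -> tuple[np.ndarray, list[str]]:
    if isinstance(features, pd.DataFrame):
        names = [str(c) for c in features.columns]
        if len(set(names)) != len(names):
            raise ValueError("feature column names must be unique")
        x = features.to_numpy(dtype=float)
    else:
        x = np.asarray(features, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        names = [f"f{i}" for i in range(x.shape[1])]
    if not np.all(np.isfinite(x)):
        raise ValueError("features contain NaN or Inf")
    return x, names


def _positive_first(classes: np.ndarray, positive_label) -> np.ndarray:
    """Order classes so the positive (patient) class comes first."""
    classes = list(classes)
    if positive_label in classes:
        classes.remove(positive_label)
        classes = [positive_label] + classes
    return np.asarray(classes)


class TTestFeatureSelector(BaseEstimator, SelectorMixin):
    """Keep features whose two-sample t-test p-value is below ``alpha``.

    The screen mirrors discriminant-feature selection at p < alpha
    (uncorrected). ``alpha=1`` keeps every column. Raises if no feature
    survives.
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError(f"need exactly 2 classes, got {classes.size}")
        a, b = X[y == classes[0]], X[y == classes[1]]
        with np.errstate(divide="ignore", invalid="ignore"):
            _, p = sps.ttest_ind(a, b, axis=0, equal_var=True)
        p = np.where(np.isfinite(p), p, 1.0)
        self.p_values_ = p
        self.support_ = p < self.alpha if self.alpha < 1 else np.ones(p.size, bool)
        if not self.support_.any():
            raise ValueError(
                f"no feature passed the t-test screen at alpha={self.alpha}"
            )
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


class MldaClassifier(BaseEstimator, ClassifierMixin):
    """Maximum-uncertainty linear discriminant analysis.

    The pooled within-class covariance S_p is eigendecomposed and every
    eigenvalue below the mean eigenvalue is raised to that mean
    (maximum-entropy covariance selection), giving a repaired S* that is
    always invertible; the discriminant is w = S*^-1 (mu1 - mu2) with
    threshold w.(mu1 + mu2)/2 (equal priors). When all eigenvalues are
    at least the mean (e.g. spherical S_p), S* = S_p and the classifier
    equals classical LDA. Ties at the threshold go to class 1 (the
    positive class, ``positive_label`` if present among the labels).
    """

    def __init__(self, positive_label="patient"):
        self.positive_label = positive_label

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError(f"MLDA is two-class; got {classes.size} classes")
        self.classes_ = _positive_first(classes, self.positive_label)
        n1 = int((y == self.classes_[0]).sum())
        n2 = int((y == self.classes_[1]).sum())
        if min(n1, n2) < 2:
            raise ValueError("each class needs at least 2 subjects")
        x1 = X[y == self.classes_[0]]
        x2 = X[y == self.classes_[1]]
        mu1, mu2 = x1.mean(axis=0), x2.mean(axis=0)
        sp = ((n1 - 1) * np.cov(x1, rowvar=False, ddof=1).reshape(X.shape[1], -1)
              + (n2 - 1) * np.cov(x2, rowvar=False, ddof=1).reshape(X.shape[1], -1)
              ) / (n1 + n2 - 2)
        evals, evecs = np.linalg.eigh((sp + sp.T) / 2)
        lam_bar = evals.mean()
        if lam_bar <= 0:
            raise ValueError("degenerate features: pooled covariance is zero")
        repaired = np.maximum(evals, lam_bar)
        s_star = (evecs * repaired) @ evecs.T
        self.class_means_ = np.stack([mu1, mu2])
        self.pooled_covariance_ = sp
        self.repaired_covariance_ = s_star
        self.coef_ = np.linalg.solve(s_star, mu1 - mu2)
        self.threshold_ = float(self.coef_ @ (mu1 + mu2) / 2)
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        return X @ self.coef_ - self.threshold_

    def predict(self, X):
        score = self.decision_function(X)
        # ties (score exactly 0) go to class 1
        return np.where(score >= 0, self.classes_[0], self.classes_[1])


def select_features(features, labels, alpha: float = 0.05):
    """Column subset passing the two-sample t-test screen (p < alpha)."""
    x, names = _as_matrix(features)
    sel = TTestFeatureSelector(alpha=alpha).fit(x, np.asarray(labels))
    return [n for n, keep in zip(names, sel.support_) if keep]


def mlda_fit(features, labels, positive_label="patient") -> MldaClassifier:
    """Fit an :class:`MldaClassifier` (functional convenience wrapper)."""
    x, _ = _as_matrix(features)
    return MldaClassifier(positive_label=positive_label).fit(x, np.asarray(labels))


def mlda_predict(model: MldaClassifier, features) -> np.ndarray:
    x, _ = _as_matrix(features)
    return model.predict(x)


def feature_weights(model: MldaClassifier, feature_names=None) -> pd.DataFrame:
    """Per-feature |w|, raw and normalized to unit Euclidean norm.

    For single-feature models the normalized weight is 1.
    """
    check_is_fitted(model, "coef_")
    w = np.abs(model.coef_)
    norm = np.linalg.norm(w)
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(w.size)]
    return pd.DataFrame(
        {
            "feature": list(feature_names),
            "weight_raw": model.coef_,
            "weight_abs": w,
            "weight_normalized": w / norm if norm > 0 else w,
        }
    )


@dataclass
class ClassificationReport:
    """LOOCV outcome, optionally with permutation significance."""

    accuracy: float
    sensitivity: float  # positive class = patient
    specificity: float
    n_subjects: int
    predictions: pd.DataFrame  # subject index, true label, predicted label
    selected_features: list[str]  # from the final whole-sample fit
    weights: pd.DataFrame  # feature weights of the whole-sample fit
    selection_mode: str  # 'nested' or 'whole-sample'
    z_score: float | None = None
    permutation_p: float | None = None
    n_permutations: int | None = None
    null_accuracies: np.ndarray | None = field(default=None, repr=False)


def _loocv_accuracy(
    x: np.ndarray,
    y: np.ndarray,
    nested_selection: bool,
    alpha: float,
    positive_label,
) -> tuple[float, float, float, np.ndarray]:
    """Core LOOCV loop; returns (accuracy, sensitivity, specificity, preds)."""
    n = x.shape[0]
    if n < 4:
        raise ValueError("LOOCV needs at least 4 subjects")
    if not nested_selection:
        sel = TTestFeatureSelector(alpha=alpha).fit(x, y)
        x_used = x[:, sel.support_]
    preds = np.empty(n, dtype=object)
    idx = np.arange(n)
    for i in range(n):
        train = idx != i
        if nested_selection:
            sel = TTestFeatureSelector(alpha=alpha).fit(x[train], y[train])
            xt, xi = x[train][:, sel.support_], x[i][sel.support_]
        else:
            xt, xi = x_used[train], x_used[i]
        clf = MldaClassifier(positive_label=positive_label).fit(xt, y[train])
        preds[i] = clf.predict(xi[None, :])[0]
    pos = positive_label if positive_label in set(y.tolist()) else np.unique(y)[0]
    is_pos = y == pos
    tp = np.sum((preds == y) & is_pos)
    tn = np.sum((preds == y) & ~is_pos)
    acc = float((tp + tn) / n)
    sens = float(tp / is_pos.sum()) if is_pos.any() else float("nan")
    spec = float(tn / (~is_pos).sum()) if (~is_pos).any() else float("nan")
    return acc, sens, spec, preds


def loocv(
    features,
    labels,
    nested_selection: bool = True,
    alpha: float = 0.05,
    positive_label="patient",
) -> ClassificationReport:
    """Leave-one-out cross-validation of the select-then-MLDA pipeline.

    With ``nested_selection`` (default) the t-test screen is re-run on
    every training fold; with ``nested_selection=False`` (whole-sample mode)
    features are selected once on the whole sample before the loop.
    Sensitivity counts the patient class as positive. The report also
    carries the whole-sample fit's selected features and weights.
    """
    x, names = _as_matrix(features)
    y = np.asarray(labels)
    acc, sens, spec, preds = _loocv_accuracy(x, y, nested_selection, alpha, positive_label)
    sel = TTestFeatureSelector(alpha=alpha).fit(x, y)
    final = MldaClassifier(positive_label=positive_label).fit(x[:, sel.support_], y)
    kept = [n for n, keep in zip(names, sel.support_) if keep]
    return ClassificationReport(
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        n_subjects=x.shape[0],
        predictions=pd.DataFrame({"index": np.arange(x.shape[0]), "true": y, "predicted": preds}),
        selected_features=kept,
        weights=feature_weights(final, kept),
        selection_mode="nested" if nested_selection else "whole-sample",
    )


def permutation_significance(
    features,
    labels,
    n_perm: int = 1000,
    seed: int | np.random.SeedSequence = 0,
    nested_selection: bool = True,
    alpha: float = 0.05,
    positive_label="patient",
) -> ClassificationReport:
    """LOOCV accuracy significance by label permutation.

    The full pipeline (selection + MLDA + LOOCV) is re-run under each of
    ``n_perm`` seeded label permutations; z = (acc_obs - mean(acc_null))
    / sd(acc_null) and p = (1 + #{acc_null >= acc_obs}) / (1 + n_perm).
    Permutations where no feature passes the screen score chance (0.5).
    A degenerate null (sd = 0) yields an infinite z with a warning.
    """
    x, _ = _as_matrix(features)
    y = np.asarray(labels)
    report = loocv(features, labels, nested_selection, alpha, positive_label)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for k in range(n_perm):
        yp = y[rng.permutation(y.size)]
        try:
            null[k], _, _, _ = _loocv_accuracy(x, yp, nested_selection, alpha, positive_label)
        except ValueError:
            null[k] = 0.5  # screen kept nothing: no better than chance
    sd = float(null.std(ddof=1))
    if sd == 0:
        warnings.warn("degenerate permutation null (sd = 0); z is infinite", stacklevel=2)
        z = float("inf") if report.accuracy > null.mean() else float("-inf")
    else:
        z = float((report.accuracy - null.mean()) / sd)
    report.z_score = z
    report.permutation_p = float((1 + np.sum(null >= report.accuracy - 1e-12)) / (1 + n_perm))
    report.n_permutations = n_perm
    report.null_accuracies = null
    return report
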