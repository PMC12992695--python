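"""Linear discriminant analysis of locomotor states.

The model is presented statsmodels-style: :class:`LocomotorLDA` is built
from a sample matrix and labels and ``fit()`` returns an
:class:`LDAResults` carrying the discriminant directions, class means,
priors and diagnostics, with ``summary()`` for a readable report. Class
merging (e.g. akinesia+stationary -> non-gait for the kinematic model,
gait+stationary -> active for the neural model), permutation feature
importance on balanced accuracy, and fold-averaged confusion matrices
follow the cross-validated evaluation design.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.inspection import permutation_importance as _sk_permutation_importance
from sklearn.metrics import (balanced_accuracy_score, confusion_matrix,
                             f1_score, precision_score, recall_score)

from .core import ConfusionSummary, ImportanceTable
from .errors import ConfigurationError, InsufficientDataError

GAIT_MERGE = {"gait": "gait", "stationary": "non-gait", "akinesia": "non-gait"}
AKINESIA_MERGE = {"gait": "active", "stationary": "active", "akinesia": "akinesia"}


def merge_classes(labels, mapping: dict[str, str]) -> np.ndarray:
    """Replace labels per mapping; every observed label must be covered."""
    labels = np.asarray(labels, dtype=object)
    observed = set(labels.tolist())
    missing = observed - set(mapping)
    if missing:
        raise ConfigurationError(f"mapping does not cover labels {sorted(missing)}")
    return np.array([mapping[l] for l in labels], dtype=object)


class LocomotorLDA:
    """LDA state classifier over a feature block.

    Prediction is by maximum class posterior under shared-covariance
    Gaussians; analytic covariance shrinkage is applied automatically when
    the pooled covariance is ill-conditioned (condition number > 1e8).
    """

    def __init__(self, X, y, feature_names: list[str] | None = None,
                 cond_threshold: float = 1e8):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=object)
        if self.X.ndim != 2 or len(self.y) != self.X.shape[0]:
            raise ConfigurationError("X must be (samples x features) matching y")
        self.feature_names = (list(feature_names) if feature_names is not None
                              else [f"x{j}" for j in range(self.X.shape[1])])
        classes, counts = np.unique(self.y, return_counts=True)
        if len(classes) < 2:
            raise InsufficientDataError("need at least 2 classes")
        if counts.min() < 2:
            raise InsufficientDataError("every class needs at least 2 samples")
        self.cond_threshold = cond_threshold

    def _pooled_cov(self) -> np.ndarray:
        cov = np.zeros((self.X.shape[1], self.X.shape[1]))
        n = 0
        for c in np.unique(self.y):
            xc = self.X[self.y == c]
            cov += (len(xc) - 1) * np.cov(xc, rowvar=False, ddof=1)
            n += len(xc) - 1
        return np.atleast_2d(cov / max(n, 1))

    def fit(self) -> "LDAResults":
        cov = self._pooled_cov()
        cond = np.linalg.cond(cov)
        shrinkage_used = None
        if np.isfinite(cond) and cond <= self.cond_threshold:
            est = LinearDiscriminantAnalysis(solver="eigen")
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    est.fit(self.X, self.y)
            except np.linalg.LinAlgError:
                est = None
        else:
            est = None
        if est is None:
            est = LinearDiscriminantAnalysis(solver="eigen", shrinkage="auto")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est.fit(self.X, self.y)
            shrinkage_used = "auto (ill-conditioned pooled covariance)"
        return LDAResults(self, est, shrinkage_used, cond)


class LDAResults:
    """Fitted LDA: directions, class statistics, prediction and summary."""

    def __init__(self, model: LocomotorLDA, estimator, shrinkage_used, cond):
        self.model = model
        self.estimator = estimator
        self.shrinkage_used = shrinkage_used
        self.pooled_condition_number = float(cond)
        self.classes_ = list(estimator.classes_)
        self.class_means = estimator.means_
        self.priors = estimator.priors_
        # directions/scalings, at most C-1 informative
        k = len(self.classes_) - 1
        self.directions = estimator.scalings_[:, :k]

    def predict(self, X) -> np.ndarray:
        return self.estimator.predict(np.asarray(X, dtype=float))

    def transform(self, X) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.directions

    def summary(self) -> str:
        lines = ["Linear discriminant analysis of locomotor states",
                 "=" * 49,
                 f"samples: {self.model.X.shape[0]}   features: {self.model.X.shape[1]}",
                 f"classes: {', '.join(map(str, self.classes_))}",
                 "priors:  " + ", ".join(f"{p:.3f}" for p in self.priors),
                 f"pooled covariance condition number: {self.pooled_condition_number:.3g}",
                 f"shrinkage: {self.shrinkage_used or 'none'}",
                 "", "top loadings on first discriminant:"]
        load = np.abs(self.directions[:, 0])
        order = np.argsort(-load)[:min(5, len(load))]
        for j in order:
            lines.append(f"  {self.model.feature_names[j]:40s} {self.directions[j, 0]:+.4f}")
        return "\n".join(lines)


def metrics_from_predictions(y_true, y_pred, positive_class: str,
                             class_order: list[str] | None = None) -> dict:
    """Positive-class metrics plus a row-normalized confusion matrix."""
    y_test = np.asarray(y_true, dtype=object)
    pred = np.asarray(y_pred, dtype=object)
    if class_order is None:
        class_order = sorted(set(y_test.tolist()) | set(pred.tolist()))
    if positive_class not in class_order:
        raise ConfigurationError(f"unknown positive class {positive_class!r}")
    if positive_class not in set(y_test.tolist()):
        return {"defined": False, "reason": f"{positive_class!r} absent from test labels"}
    cm = confusion_matrix(y_test, pred, labels=class_order).astype(float)
    row_sums = cm.sum(axis=1, keepdims=True)
    cm_norm = np.divide(cm, row_sums, out=np.full_like(cm, np.nan), where=row_sums > 0)
    # average="macro" over a single label == the per-class (positive-class) score
    kw = dict(labels=[positive_class], average="macro", zero_division=0)
    return {
        "defined": True,
        "classes": list(class_order),
        "confusion": cm_norm,
        "precision": float(precision_score(y_test, pred, **kw)),
        "recall": float(recall_score(y_test, pred, **kw)),
        "f1": float(f1_score(y_test, pred, **kw)),
        "f1_macro": float(f1_score(y_test, pred, average="macro", zero_division=0)),
        "balanced_accuracy": float(balanced_accuracy_score(y_test, pred)),
    }


def evaluate_classifier(results: LDAResults, X_test, y_test,
                        positive_class: str,
                        class_order: list[str] | None = None) -> dict:
    """Predict with a fitted LDA and score against the positive class."""
    if class_order is None:
        class_order = results.classes_
    return metrics_from_predictions(y_test, results.predict(X_test),
                                    positive_class, class_order)


def permutation_importance(results: LDAResults, X_test, y_test,
                           n_repeats: int = 10, seed: int = 0) -> pd.Series:
    """Mean drop in balanced accuracy over independent column permutations."""
    if n_repeats < 1:
        raise ConfigurationError("n_repeats must be >= 1")
    with warnings.catch_warnings():
        # scoring emits a warning when a permuted prediction drops a class
        warnings.simplefilter("ignore", UserWarning)
        out = _sk_permutation_importance(
            results.estimator, np.asarray(X_test, dtype=float),
            np.asarray(y_test, dtype=object), scoring="balanced_accuracy",
            n_repeats=n_repeats, random_state=seed)
    return pd.Series(out.importances_mean, index=results.model.feature_names)


def cross_validated_lda(X, y, runs, plan, positive_class: str,
                        feature_names: list[str] | None = None,
                        n_repeats: int = 10, seed: int = 0,
                        compute_importance: bool = True,
                        eval_merge: dict[str, str] | None = None):
    """Fit/evaluate LDA over a run-grouped split plan.

    The model is fitted on the full label vocabulary; ``eval_merge``
    optionally collapses classes for reporting only (e.g. akinesia +
    stationary -> non-gait), mirroring the practice of grouping confounded
    states in the confusion matrix while the classifier itself stays
    multiclass. Importance is always computed on the unmerged problem.
    Returns ``(metrics DataFrame, ConfusionSummary, ImportanceTable | None)``.
    Folds where the positive class is absent from the test partition are
    recorded and skipped for binary metrics.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    runs = np.asarray(runs, dtype=object)
    rows, matrices, fold_importances = [], [], []
    y_eval_all = merge_classes(y, eval_merge) if eval_merge else y
    class_order = sorted(set(y_eval_all.tolist()))
    for fold_id, (train_runs, test_runs) in enumerate(plan.folds):
        tr = np.isin(runs, train_runs)
        te = np.isin(runs, test_runs)
        res = LocomotorLDA(X[tr], y[tr], feature_names).fit()
        pred = res.predict(X[te])
        if eval_merge:
            pred = merge_classes(pred, eval_merge)
        ev = metrics_from_predictions(y_eval_all[te], pred, positive_class,
                                      class_order)
        if not ev["defined"]:
            rows.append({"fold": fold_id, "defined": False})
            continue
        if not np.isnan(ev["confusion"]).any():
            matrices.append(ev["confusion"])
        rows.append({"fold": fold_id, "defined": True, "f1": ev["f1"],
                     "precision": ev["precision"], "recall": ev["recall"],
                     "f1_macro": ev["f1_macro"],
                     "balanced_accuracy": ev["balanced_accuracy"]})
        if compute_importance:
            fold_importances.append(
                permutation_importance(res, X[te], y[te], n_repeats, seed + fold_id))
    metrics = pd.DataFrame(rows)
    confusion = ConfusionSummary(class_order, matrices) if matrices else None
    importance = (ImportanceTable.from_fold_series(fold_importances)
                  if fold_importances else None)
    return metrics, confusion, importance
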