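"""Cross-validated benchmarking of the five classifier families.

The protocol mirrors a standard tabular screening pipeline: Tukey-fence
winsorization of outliers (replaced by the 25th/75th percentile values),
standard scaling, PCA to 95% retained variance, then stratified 10-fold
cross-validation with an exhaustive hyperparameter grid search per family.
All preprocessing is fitted on training folds only and applied to the
held-out fold, so no information leaks across the split.

Quantitative criteria per model: accuracy, precision, recall, specificity
and F1 from the held-out confusion matrices, ROC-AUC from held-out decision
scores (trapezoidal rule), and negated log loss from held-out class
probabilities (natural log, probabilities clipped at 1e-15).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin, clone
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss as sk_log_loss
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import ParameterGrid, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "MODEL_FAMILIES",
    "ConfusionMatrix",
    "MetricsReport",
    "ModelSpec",
    "Winsorizer",
    "winsorize_outliers",
    "metrics_from_confusion",
    "pca_reduce",
    "evaluate_cv",
    "grid_search",
    "default_model_specs",
    "run_benchmark",
]

logger = logging.getLogger(__name__)

MODEL_FAMILIES = ("svm", "random_forest", "logistic_regression",
                  "knn", "naive_bayes")

_PROB_CLIP = 1e-15


# ---------------------------------------------------------------------------
# Outlier winsorization
# ---------------------------------------------------------------------------

def winsorize_outliers(column, fence_multiplier: float = 1.5,
                       name: str | None = None) -> np.ndarray:
    """Replace Tukey-fence outliers by quartile values.

    Values below Q1 - k*IQR become the 25th-percentile value; values above
    Q3 + k*IQR become the 75th-percentile value (k = ``fence_multiplier``).
    Quartiles use linear interpolation. All other values pass through.
    """
    col = np.asarray(column)
    label = f" in column {name!r}" if name else ""
    if col.dtype == object or not np.issubdtype(col.dtype, np.number):
        raise ValueError(f"non-numeric entries{label}; winsorization "
                         "requires a numeric column")
    col = col.astype(float)
    if col.size < 4:
        raise ValueError(f"winsorization{label} requires at least 4 values, "
                         f"got {col.size}")
    if np.isnan(col).any():
        raise ValueError(f"missing values{label}; impute before winsorizing")
    q1, q3 = np.percentile(col, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - fence_multiplier * iqr, q3 + fence_multiplier * iqr
    return np.where(col < lo, q1, np.where(col > hi, q3, col))


class Winsorizer(BaseEstimator, TransformerMixin):
    """Column-wise Tukey winsorizer with fences learned at fit time.

    Learning the quartiles and fences on the training folds and re-applying
    them to held-out data keeps the cross-validation leakage-free.
    """

    def __init__(self, fence_multiplier: float = 1.5):
        self.fence_multiplier = fence_multiplier

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.q1_, self.q3_ = np.percentile(X, [25, 75], axis=0)
        iqr = self.q3_ - self.q1_
        self.lo_ = self.q1_ - self.fence_multiplier * iqr
        self.hi_ = self.q3_ + self.fence_multiplier * iqr
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return np.where(X < self.lo_, self.q1_,
                        np.where(X > self.hi_, self.q3_, X))


# ---------------------------------------------------------------------------
# Confusion-matrix metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts of a binary classification outcome (positive class = 1)."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        counts = (self.tp, self.tn, self.fp, self.fn)
        if any(c < 0 for c in counts):
            raise ValueError(f"confusion counts must be non-negative: {self}")
        if sum(counts) == 0:
            raise ValueError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _ratio(num: float, den: float, metric: str) -> float:
    if den == 0:
        warnings.warn(f"{metric} is undefined (zero denominator); "
                      "reporting NaN", RuntimeWarning, stacklevel=3)
        return float("nan")
    return num / den


def metrics_from_confusion(cm: ConfusionMatrix) -> dict[str, float]:
    """Accuracy, precision, recall, specificity and F1 from raw counts.

    accuracy = (TP+TN)/(TP+FP+FN+TN); precision = TP/(TP+FP);
    recall = TP/(TP+FN); specificity = TN/(TN+FP);
    F1 = 2*precision*recall/(precision+recall).
    A metric whose denominator vanishes is reported as NaN (undefined,
    distinct from zero) with a warning naming it.
    """
    precision = _ratio(cm.tp, cm.tp + cm.fp, "precision")
    recall = _ratio(cm.tp, cm.tp + cm.fn, "recall")
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        if precision + recall == 0 and not (np.isnan(precision) or np.isnan(recall)):
            warnings.warn("f1 is undefined (precision + recall = 0); "
                          "reporting NaN", RuntimeWarning, stacklevel=2)
        f1 = float("nan")
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return {
        "accuracy": _ratio(cm.tp + cm.tn, cm.total, "accuracy"),
        "precision": precision,
        "recall": recall,
        "specificity": _ratio(cm.tn, cm.tn + cm.fp, "specificity"),
        "f1": f1,
    }


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca_reduce(features, variance_retained: float = 0.95):
    """Project onto the leading principal components.

    Keeps the smallest number of components whose cumulative explained
    variance ratio reaches ``variance_retained``; 1.0 keeps the full basis
    (min(n_samples - 1, n_features) components). Columns are centered by the
    fitted transform, which is reusable on held-out data.

    Returns ``(reduced, fitted_pca)``.
    """
    X = np.asarray(features, dtype=float)
    if not 0.0 < variance_retained <= 1.0:
        raise ValueError("variance_retained must lie in (0, 1]")
    if variance_retained == 1.0:
        n_components = min(X.shape[0] - 1, X.shape[1])
    else:
        n_components = variance_retained
    pca = PCA(n_components=n_components, svd_solver="full")
    reduced = pca.fit_transform(X)
    return reduced, pca


# ---------------------------------------------------------------------------
# Model families and grids
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """A classifier family plus its hyperparameter grid (named value lists)."""

    family: str
    grid: dict[str, list] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}; "
                             f"choose from {MODEL_FAMILIES}")
        for key, values in self.grid.items():
            if not list(values):
                raise ValueError(f"empty grid for parameter {key!r}")


def default_model_specs() -> dict[str, ModelSpec]:
    """Default grids: k in 1..41 for KNN, C in {0.1, 1, 10, 100} with an RBF
    kernel for SVM, n_estimators in {5, 10, 50, 100} for random forest;
    logistic regression and Gaussian naive Bayes stay at library defaults."""
    return {
        "svm": ModelSpec("svm", {"C": [0.1, 1, 10, 100], "kernel": ["rbf"]}),
        "random_forest": ModelSpec("random_forest",
                                   {"n_estimators": [5, 10, 50, 100]}),
        "logistic_regression": ModelSpec("logistic_regression", {}),
        "knn": ModelSpec("knn", {"n_neighbors": list(range(1, 42))}),
        "naive_bayes": ModelSpec("naive_bayes", {}),
    }


def _make_estimator(family: str, params: Mapping[str, object], seed: int):
    params = dict(params)
    if family == "svm":
        return SVC(probability=True, random_state=seed, **params)
    if family == "random_forest":
        return RandomForestClassifier(random_state=seed, **params)
    if family == "logistic_regression":
        return LogisticRegression(max_iter=5000, **params)
    if family == "knn":
        return KNeighborsClassifier(**params)
    if family == "naive_bayes":
        return GaussianNB(**params)
    raise ValueError(f"unknown model family {family!r}")


def make_pipeline(family: str, params: Mapping[str, object] | None = None,
                  seed: int = 42, variance_retained: float = 0.95) -> Pipeline:
    """Leakage-free pipeline: winsorize -> scale -> PCA -> classifier."""
    return Pipeline([
        ("winsorize", Winsorizer()),
        ("scale", StandardScaler()),
        ("pca", PCA(n_components=variance_retained, svd_solver="full")),
        ("clf", _make_estimator(family, params or {}, seed)),
    ])


# ---------------------------------------------------------------------------
# Cross-validated evaluation
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """Cross-validated performance of one model (all rates as fractions).

    ``f1`` is the harmonic mean of the reported precision and recall;
    ``neg_log_loss`` is the negated natural-log loss (larger, i.e. closer
    to 0, is better); ``support`` counts true samples per class.
    """

    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    roc_auc: float
    neg_log_loss: float
    support: dict[int, int]

    def as_dict(self) -> dict[str, float]:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "specificity": self.specificity,
                "f1": self.f1, "roc_auc": self.roc_auc,
                "neg_log_loss": self.neg_log_loss}


def _split_xy(dataset: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    if "label" not in dataset.columns:
        raise ValueError('dataset must contain a "label" column with values 0/1')
    y = dataset["label"].to_numpy()
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError(f"labels must be 0/1, got {sorted(set(y))}")
    if len(np.unique(y)) < 2:
        raise ValueError("dataset must contain both classes")
    X = dataset.drop(columns=["label"])
    non_numeric = [c for c in X.columns
                   if not np.issubdtype(X[c].dtype, np.number)]
    if non_numeric:
        raise ValueError(f"non-numeric feature columns: {non_numeric}")
    return X.to_numpy(dtype=float), y.astype(int)


def evaluate_cv(dataset: pd.DataFrame,
                spec: ModelSpec | str,
                params: Mapping[str, object] | None = None,
                folds: int = 10,
                seed: int = 42,
                variance_retained: float = 0.95,
                aggregate: str = "folds") -> MetricsReport:
    """Stratified k-fold evaluation of one family at fixed hyperparameters.

    Winsorization, scaling and PCA are fitted on each training split only.
    ``aggregate="folds"`` (default) averages metrics over folds, with F1
    recomputed as the harmonic mean of the averaged precision and recall;
    ``aggregate="pooled"`` sums the held-out confusion matrices and pools
    scores before computing metrics once. Fixed seed gives bit-identical
    fold assignments and metric values.
    """
    family = spec.family if isinstance(spec, ModelSpec) else spec
    if aggregate not in ("folds", "pooled"):
        raise ValueError('aggregate must be "folds" or "pooled"')
    X, y = _split_xy(dataset)
    class_counts = np.bincount(y, minlength=2)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if class_counts.min() < folds:
        raise ValueError(
            f"smallest class has {class_counts.min()} members, fewer than "
            f"{folds} folds; use fewer folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pipeline = make_pipeline(family, params, seed=seed,
                             variance_retained=variance_retained)

    cms, aucs, nlls = [], [], []
    pooled_proba = np.empty(len(y))
    pooled_pred = np.empty(len(y), dtype=int)
    for train_idx, test_idx in skf.split(X, y):
        model = clone(pipeline)
        model.fit(X[train_idx], y[train_idx])
        pred = model.predict(X[test_idx])
        proba = model.predict_proba(X[test_idx])[:, 1]
        y_test = y[test_idx]
        cms.append(ConfusionMatrix(
            tp=int(np.sum((pred == 1) & (y_test == 1))),
            tn=int(np.sum((pred == 0) & (y_test == 0))),
            fp=int(np.sum((pred == 1) & (y_test == 0))),
            fn=int(np.sum((pred == 0) & (y_test == 1))),
        ))
        aucs.append(roc_auc_score(y_test, proba))
        clipped = np.clip(proba, _PROB_CLIP, 1.0 - _PROB_CLIP)
        nlls.append(sk_log_loss(y_test, clipped, labels=[0, 1]))
        pooled_proba[test_idx] = proba
        pooled_pred[test_idx] = pred

    if aggregate == "pooled":
        cm = ConfusionMatrix(tp=sum(c.tp for c in cms), tn=sum(c.tn for c in cms),
                             fp=sum(c.fp for c in cms), fn=sum(c.fn for c in cms))
        m = metrics_from_confusion(cm)
        auc = roc_auc_score(y, pooled_proba)
        nll = sk_log_loss(y, np.clip(pooled_proba, _PROB_CLIP, 1 - _PROB_CLIP),
                          labels=[0, 1])
    else:
        per_fold = [metrics_from_confusion(c) for c in cms]
        m = {k: float(np.nanmean([pf[k] for pf in per_fold]))
             for k in ("accuracy", "precision", "recall", "specificity")}
        m["f1"] = (2 * m["precision"] * m["recall"]
                   / (m["precision"] + m["recall"]))
        auc = float(np.mean(aucs))
        nll = float(np.mean(nlls))

    return MetricsReport(
        accuracy=m["accuracy"], precision=m["precision"], recall=m["recall"],
        specificity=m["specificity"], f1=m["f1"],
        roc_auc=float(auc), neg_log_loss=-float(nll),
        support={0: int(class_counts[0]), 1: int(class_counts[1])},
    )


def grid_search(dataset: pd.DataFrame,
                spec: ModelSpec,
                folds: int = 10,
                seed: int = 42,
                variance_retained: float = 0.95) -> tuple[dict, MetricsReport]:
    """Exhaustive search over ``spec.grid``, selecting by mean CV accuracy.

    Ties break deterministically in favor of the first-listed grid entry.
    Returns ``(best_params, report_at_best_params)``.
    """
    best_params, best_report, best_acc = None, None, -np.inf
    for params in ParameterGrid(spec.grid if spec.grid else {}):
        report = evaluate_cv(dataset, spec, params, folds=folds, seed=seed,
                             variance_retained=variance_retained)
        if report.accuracy > best_acc:
            best_params, best_report, best_acc = dict(params), report, report.accuracy
    logger.info("grid search %s: best params %s (CV accuracy %.4f)",
                spec.family, best_params, best_acc)
    return best_params, best_report


def run_benchmark(dataset: pd.DataFrame,
                  specs: Mapping[str, ModelSpec] | None = None,
                  folds: int = 10,
                  seed: int = 42,
                  variance_retained: float = 0.95,
                  ) -> dict[str, tuple[dict, MetricsReport]]:
    """Grid-search every family and return per-family (best params, report)."""
    specs = specs or default_model_specs()
    results = {}
    for family, spec in specs.items():
        results[family] = grid_search(dataset, spec, folds=folds, seed=seed,
                                      variance_retained=variance_retained)
    return results
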