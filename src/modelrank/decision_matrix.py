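"""Assembly of the ten-criterion decision matrix for classifier selection.

The matrix mixes six quantitative criteria measured by cross-validated
benchmarking (accuracy, recall, precision, F1, ROC-AUC as percentages; log
loss as a raw negated value, to be minimized) with four qualitative criteria
coded on a 0-1 scale from the model-selection literature: the number of
training samples needed (NOTS), the impact of feature scaling (IOFS), the
impact of hyper-parameter tuning (IOHT, a YES/NO flag), and tolerance to
irrelevant attributes (TTIA).

Criterion importances follow the five-level linguistic scale: the six
performance criteria are Very High, NOTS/IOFS/IOHT are High, and TTIA is
Medium. Two reference matrices from a published five-classifier breast
cancer screening benchmark (Wisconsin diagnostic fine-needle-aspirate data
and the BIRADS mammographic-mass data) are bundled as worked examples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

from .fuzzy import DEFAULT_SCALE, LinguisticScale, defuzzify
from .promethee import Criterion, DecisionMatrix

__all__ = [
    "METRIC_CRITERIA",
    "QUALITATIVE_CRITERIA",
    "CRITERIA_ORDER",
    "DEFAULT_WEIGHT_LABELS",
    "FAMILY_DISPLAY_NAMES",
    "QualitativeCriteriaTable",
    "encode_qualitative",
    "default_criteria",
    "criteria_from_config",
    "default_qualitative_table",
    "assemble",
    "wisconsin_example",
    "mammographic_example",
]

METRIC_CRITERIA = ("accuracy", "recall", "precision", "f1_score",
                   "roc_auc", "log_loss")
QUALITATIVE_CRITERIA = ("training_samples", "feature_scaling",
                        "hyperparameter_tuning", "irrelevant_attributes")
CRITERIA_ORDER = METRIC_CRITERIA + QUALITATIVE_CRITERIA

#: Expert-elicited importance label per criterion.
DEFAULT_WEIGHT_LABELS: dict[str, str] = {
    "accuracy": "Very High",
    "recall": "Very High",
    "precision": "Very High",
    "f1_score": "Very High",
    "roc_auc": "Very High",
    "log_loss": "Very High",
    "training_samples": "High",
    "feature_scaling": "High",
    "hyperparameter_tuning": "High",
    "irrelevant_attributes": "Medium",
}

FAMILY_DISPLAY_NAMES = {
    "svm": "SVM",
    "random_forest": "Random Forest",
    "logistic_regression": "Logistic Regression",
    "knn": "KNN",
    "naive_bayes": "Naive Bayes",
}


def encode_qualitative(value) -> float:
    """Resolve a qualitative cell to a number: YES -> 1.0, NO -> 0.0, and
    numeric codes in [0, 1] pass through unchanged."""
    if isinstance(value, str):
        token = value.strip().upper()
        if token == "YES":
            return 1.0
        if token == "NO":
            return 0.0
        try:
            value = float(token)
        except ValueError:
            raise ValueError(
                f"unknown qualitative token {value!r}: expected YES, NO, "
                "or a number in [0, 1]"
            ) from None
    value = float(value)
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"qualitative code {value} outside [0, 1]")
    return value


@dataclass
class QualitativeCriteriaTable:
    """Per-family qualitative codes; values are YES/NO or reals in [0, 1]."""

    codes: Mapping[str, Mapping[str, object]]

    def __post_init__(self) -> None:
        for family, row in self.codes.items():
            for crit in QUALITATIVE_CRITERIA:
                if crit not in row:
                    raise ValueError(
                        f"family {family!r} is missing qualitative "
                        f"criterion {crit!r}"
                    )
                encode_qualitative(row[crit])  # validates
            flag = str(row["hyperparameter_tuning"]).strip().upper()
            if flag not in ("YES", "NO", "1.0", "0.0", "1", "0"):
                raise ValueError(
                    f"family {family!r}: hyperparameter_tuning must be a "
                    f"YES/NO flag, got {row['hyperparameter_tuning']!r}"
                )

    def families(self) -> list[str]:
        return list(self.codes)

    def encoded(self, family: str, criterion: str) -> float:
        return encode_qualitative(self.codes[family][criterion])


def default_qualitative_table() -> QualitativeCriteriaTable:
    """Bundled literature-derived codes for the five classifier families."""
    raw = json.loads(
        resources.files("modelrank.data").joinpath("qualitative_codes.json")
        .read_text()
    )
    raw.pop("_comment", None)
    return QualitativeCriteriaTable(raw)


def default_criteria(scale: LinguisticScale = DEFAULT_SCALE,
                     method: str = "yager") -> list[Criterion]:
    """The ten standard criteria with normalized fuzzy-derived weights.

    Every criterion is maximized on its coded or percentage value except log
    loss, which is minimized on the raw negated values; spreads are "auto".
    """
    config = [{"name": name,
               "direction": "minimize" if name == "log_loss" else "maximize",
               "weight_label": DEFAULT_WEIGHT_LABELS[name],
               "spread": "auto"}
              for name in CRITERIA_ORDER]
    return criteria_from_config(config, scale=scale, method=method)


def criteria_from_config(config: Sequence[Mapping[str, object]],
                         scale: LinguisticScale = DEFAULT_SCALE,
                         method: str = "yager") -> list[Criterion]:
    """Build criteria from config entries and normalize weights to sum 1.

    Each entry carries ``name``, ``direction``, a ``weight_label`` on the
    linguistic scale or an explicit non-negative ``weight_value``, and an
    optional ``spread`` (positive number or ``"auto"``).
    """
    if not config:
        raise ValueError("criteria configuration is empty")
    crisp = []
    for entry in config:
        if "weight_value" in entry and entry["weight_value"] is not None:
            w = float(entry["weight_value"])
            if w < 0:
                raise ValueError(
                    f"criterion {entry.get('name')!r}: weight_value must be >= 0")
        elif "weight_label" in entry and entry["weight_label"] is not None:
            w = defuzzify(scale[str(entry["weight_label"])], method)
        else:
            raise ValueError(
                f"criterion {entry.get('name')!r}: provide weight_label or "
                "weight_value")
        crisp.append(w)
    total = float(np.sum(crisp))
    if total <= 0:
        raise ValueError("criterion weights sum to zero; cannot normalize")
    return [
        Criterion(name=str(entry["name"]),
                  direction=str(entry.get("direction", "maximize")),
                  weight=w / total,
                  spread=entry.get("spread", "auto"))
        for entry, w in zip(config, crisp)
    ]


def assemble(metrics: Mapping[str, "object"],
             qual: QualitativeCriteriaTable | None = None,
             criteria: Sequence[Criterion] | None = None) -> DecisionMatrix:
    """Combine per-family metric reports and qualitative codes into a matrix.

    ``metrics`` maps family keys (e.g. ``"svm"``) to
    :class:`~modelrank.bench.MetricsReport`-like objects exposing
    ``accuracy``, ``recall``, ``precision``, ``f1``, ``roc_auc`` (fractions)
    and ``neg_log_loss``. Rate metrics enter the matrix as percentages
    (x100); log loss enters as the raw negated value. Qualitative cells pass
    through :func:`encode_qualitative`. When ``criteria`` is given it fixes
    the column subset and order; by default all ten standard criteria are
    used (which then requires ``qual``).
    """
    if criteria is None:
        criteria = default_criteria()
    metric_sources = {
        "accuracy": lambda r: r.accuracy * 100.0,
        "recall": lambda r: r.recall * 100.0,
        "precision": lambda r: r.precision * 100.0,
        "f1_score": lambda r: r.f1 * 100.0,
        "roc_auc": lambda r: r.roc_auc * 100.0,
        "log_loss": lambda r: r.neg_log_loss,
    }
    rows, names = [], []
    for family, report in metrics.items():
        row = []
        for crit in criteria:
            if crit.name in metric_sources:
                row.append(metric_sources[crit.name](report))
            elif crit.name in QUALITATIVE_CRITERIA:
                if qual is None or family not in qual.codes:
                    raise ValueError(
                        f"family {family!r} has no qualitative codes but "
                        f"criterion {crit.name!r} is configured"
                    )
                row.append(qual.encoded(family, crit.name))
            else:
                raise ValueError(f"unknown criterion {crit.name!r}")
        rows.append(row)
        names.append(FAMILY_DISPLAY_NAMES.get(family, family))
    if qual is not None:
        missing = [f for f in qual.families() if f not in metrics]
        if missing:
            raise ValueError(
                f"families present in qualitative table but missing from "
                f"metrics: {missing}"
            )
    return DecisionMatrix(names, list(criteria), np.asarray(rows, float))


# ---------------------------------------------------------------------------
# Bundled worked examples: published five-classifier screening benchmarks.
# Row order: SVM, Random Forest, Logistic Regression, KNN, Naive Bayes.
# Column order: CRITERIA_ORDER. YES/NO flags already coded 1/0.
# ---------------------------------------------------------------------------

_WISCONSIN_ROWS = {
    "SVM": [99.0, 99.0, 99.5, 99.0, 99.5, -0.828, 0.92, 0.92, 1.0, 0.92],
    "Random Forest": [97.5, 97.0, 98.0, 97.0, 99.0, -0.815, 0.75, 0.08, 1.0, 0.08],
    "Logistic Regression": [97.5, 97.0, 98.0, 97.0, 99.0, -0.815, 0.50, 0.25, 0.0, 0.50],
    "KNN": [98.0, 98.0, 98.5, 98.0, 99.0, -0.819, 0.08, 0.92, 1.0, 0.50],
    "Naive Bayes": [97.5, 97.0, 98.0, 97.0, 99.0, -0.815, 0.50, 0.08, 0.0, 0.75],
}

_BIRADS_ROWS = {
    "SVM": [97.0, 95.5, 97.5, 98.5, 99.5, -0.8110, 0.92, 0.92, 1.0, 0.92],
    "Random Forest": [96.0, 96.0, 98.0, 98.0, 99.0, -0.8026, 0.75, 0.08, 1.0, 0.08],
    "Logistic Regression": [95.5, 95.5, 97.0, 96.5, 99.0, -0.7984, 0.50, 0.25, 0.0, 0.50],
    "KNN": [95.5, 96.0, 97.5, 96.0, 98.5, -0.7990, 0.08, 0.92, 1.0, 0.50],
    "Naive Bayes": [94.0, 94.0, 96.0, 96.0, 98.0, -0.7860, 0.50, 0.08, 0.0, 0.75],
}


def _example_matrix(rows: dict[str, list[float]]) -> DecisionMatrix:
    return DecisionMatrix(list(rows), default_criteria(),
                          np.array(list(rows.values()), float))


def wisconsin_example() -> DecisionMatrix:
    """Published decision matrix of five classifier families benchmarked on
    the Wisconsin diagnostic breast cancer data (569 fine-needle-aspirate
    samples, 30 features). SVM dominates every column, so its negative
    outranking flow is exactly zero for any positive spreads."""
    return _example_matrix(_WISCONSIN_ROWS)


def mammographic_example() -> DecisionMatrix:
    """Published decision matrix of the same five families benchmarked on
    the BIRADS mammographic-mass data (961 records)."""
    return _example_matrix(_BIRADS_ROWS)
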