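"""Triangular fuzzy numbers, linguistic importance scales, and crisp criterion weights.

Criterion importances are elicited from domain experts as linguistic labels
("Very High" ... "Very Low"), represented as triangular fuzzy numbers (TFNs)
on the unit interval, defuzzified to a crisp representative value, and
normalized into a weight vector that sums to one — the form PROMETHEE II
requires so that outranking flows stay in [-1, 1].

Two defuzzification indices are provided:

* ``"yager"`` (default): the Yager F1 ranking index, the integral of the
  midpoints of the alpha-cuts of the triangular membership function, which
  for a TFN (l, m, u) has the closed form (l + 2m + u) / 4.
* ``"centroid"``: the centre of gravity (l + m + u) / 3.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "TriangularFuzzyNumber",
    "LinguisticScale",
    "DEFAULT_SCALE",
    "defuzzify_yager",
    "defuzzify_centroid",
    "defuzzify",
    "weights_from_linguistic",
]

_NORMALIZATION_TOL = 1e-12


@dataclass(frozen=True)
class TriangularFuzzyNumber:
    """A fuzzy quantity (l, m, u): membership rises linearly from ``lower``
    to 1 at ``mode`` and falls linearly to 0 at ``upper``.

    The degenerate case l = m = u is a crisp number.
    """

    lower: float
    mode: float
    upper: float

    def __post_init__(self) -> None:
        if not (self.lower <= self.mode <= self.upper):
            raise ValueError(
                f"invalid triangular fuzzy number ({self.lower}, {self.mode}, "
                f"{self.upper}): requires lower <= mode <= upper"
            )

    def alpha_cut(self, alpha: float) -> tuple[float, float]:
        """Interval of membership >= ``alpha``, for alpha in [0, 1]."""
        lo = self.lower + alpha * (self.mode - self.lower)
        hi = self.upper - alpha * (self.upper - self.mode)
        return lo, hi

    def defuzzify(self, method: str = "yager") -> float:
        return defuzzify(self, method)


def defuzzify_yager(tfn: TriangularFuzzyNumber) -> float:
    """Yager F1 index: integral over alpha in [0, 1] of the alpha-cut
    midpoint, closed form (l + 2m + u) / 4. Always lies in [l, u]."""
    return (tfn.lower + 2.0 * tfn.mode + tfn.upper) / 4.0


def defuzzify_centroid(tfn: TriangularFuzzyNumber) -> float:
    """Centre-of-gravity index (l + m + u) / 3."""
    return (tfn.lower + tfn.mode + tfn.upper) / 3.0


_DEFUZZIFIERS = {"yager": defuzzify_yager, "centroid": defuzzify_centroid}


def defuzzify(tfn: TriangularFuzzyNumber, method: str = "yager") -> float:
    try:
        fn = _DEFUZZIFIERS[method]
    except KeyError:
        raise ValueError(
            f"unknown defuzzification method {method!r}; "
            f"choose from {sorted(_DEFUZZIFIERS)}"
        ) from None
    return fn(tfn)


class LinguisticScale:
    """Ordered five-level mapping from importance labels to TFNs.

    The canonical scale runs Very High, High, Medium, Low, Very Low; the
    defuzzified values must be strictly decreasing in that order so that a
    "higher" label always yields a larger weight.
    """

    LABELS = ("Very High", "High", "Medium", "Low", "Very Low")
    _ALIASES = {"VH": "Very High", "H": "High", "M": "Medium",
                "L": "Low", "VL": "Very Low"}

    def __init__(self, mapping: Mapping[str, TriangularFuzzyNumber],
                 defuzzifier: str = "yager") -> None:
        missing = [lab for lab in self.LABELS if lab not in mapping]
        extra = [lab for lab in mapping if lab not in self.LABELS]
        if missing or extra:
            raise ValueError(
                f"linguistic scale must contain exactly the labels "
                f"{list(self.LABELS)}; missing={missing}, unexpected={extra}"
            )
        self._mapping = {lab: mapping[lab] for lab in self.LABELS}
        values = [defuzzify(self._mapping[lab], defuzzifier) for lab in self.LABELS]
        if not all(a > b for a, b in zip(values, values[1:])):
            raise ValueError(
                "defuzzified scale values must be strictly decreasing from "
                f"Very High to Very Low; got {values}"
            )

    def __getitem__(self, label: str) -> TriangularFuzzyNumber:
        return self._mapping[self.resolve(label)]

    def __iter__(self):
        return iter(self._mapping)

    def items(self):
        return self._mapping.items()

    def resolve(self, label: str) -> str:
        """Normalize a label or its abbreviation (case-insensitive)."""
        key = label.strip()
        for canonical in self.LABELS:
            if key.lower() == canonical.lower():
                return canonical
        upper = key.upper()
        if upper in self._ALIASES:
            return self._ALIASES[upper]
        raise KeyError(
            f"unknown linguistic label {label!r}; valid labels are "
            f"{list(self.LABELS)} (abbreviations {sorted(self._ALIASES)})"
        )


#: Unit-interval importance scale used throughout: the standard five-level
#: triangular partition of [0, 1] with a saturated top and bottom level.
DEFAULT_SCALE = LinguisticScale({
    "Very High": TriangularFuzzyNumber(0.75, 1.0, 1.0),
    "High": TriangularFuzzyNumber(0.50, 0.75, 1.0),
    "Medium": TriangularFuzzyNumber(0.25, 0.50, 0.75),
    "Low": TriangularFuzzyNumber(0.0, 0.25, 0.50),
    "Very Low": TriangularFuzzyNumber(0.0, 0.0, 0.25),
})


def weights_from_linguistic(
    labels: Sequence[str],
    scale: LinguisticScale = DEFAULT_SCALE,
    method: str = "yager",
) -> np.ndarray:
    """Defuzzify one linguistic label per criterion and normalize to sum 1.

    Order of the output matches the order of ``labels``. Raises ``KeyError``
    listing the valid labels when a label is not on the scale.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("at least one criterion label is required")
    crisp = np.array([defuzzify(scale[lab], method) for lab in labels], float)
    total = crisp.sum()
    if total <= 0:
        raise ValueError("labels defuzzify to a zero total importance; "
                         "cannot normalize to a weight vector")
    weights = crisp / total
    # guard the normalization contract rather than trusting float arithmetic
    assert abs(weights.sum() - 1.0) < _NORMALIZATION_TOL
    return weights
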