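"""PROMETHEE II outranking engine with Gaussian preference functions.

Given a decision matrix (alternatives x criteria), per-criterion optimization
directions, weights and Gaussian preference spreads, this module computes:

* pairwise deviations d_j(a, b), sign-flipped for minimize criteria;
* Gaussian preference degrees P_j(d) = 1 - exp(-d^2 / (2 s_j^2)) for d > 0,
  0 otherwise;
* aggregated preference indices pi(a, b) = sum_j w_j P_j(a, b);
* positive, negative and net outranking flows
  Phi+(a) = (1/(n-1)) sum_b pi(a, b),  Phi-(a) = (1/(n-1)) sum_b pi(b, a),
  Phi = Phi+ - Phi-;
* unicriterion net flows phi_j(a) = (1/(n-1)) sum_b [P_j(a,b) - P_j(b,a)],
  whose weighted sum reconstructs Phi(a) — the segments of the "rainbow"
  contribution decomposition;
* the complete ranking by descending net flow.

The Gaussian shape deliberately damps small deviations: a tiny edge on one
criterion translates into a near-zero preference degree, so rankings are not
driven by rounding noise in the input table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Criterion",
    "DecisionMatrix",
    "FlowTable",
    "deviation",
    "gaussian_preference",
    "preference_index",
    "resolve_spreads",
    "compute_flows",
    "rank_complete",
]

logger = logging.getLogger(__name__)

_WEIGHT_SUM_TOL = 1e-8
MAXIMIZE = "maximize"
MINIMIZE = "minimize"


@dataclass
class Criterion:
    """One column of the decision matrix.

    Parameters
    ----------
    name : criterion identifier (unique within a matrix).
    direction : ``"maximize"`` (larger is better) or ``"minimize"``.
    weight : non-negative relative importance; weights of a matrix are
        expected to sum to 1 (see :mod:`modelrank.fuzzy`).
    spread : Gaussian preference parameter s in the units of the criterion's
        column, or ``"auto"`` to use the population standard deviation of
        the column at flow-computation time.
    """

    name: str
    direction: str = MAXIMIZE
    weight: float = 1.0
    spread: float | str = "auto"

    def __post_init__(self) -> None:
        if self.direction not in (MAXIMIZE, MINIMIZE):
            raise ValueError(
                f"criterion {self.name!r}: direction must be "
                f"'maximize' or 'minimize', got {self.direction!r}"
            )
        if self.weight < 0:
            raise ValueError(f"criterion {self.name!r}: weight must be >= 0")
        if self.spread != "auto":
            if not np.isfinite(self.spread) or self.spread <= 0:
                raise ValueError(
                    f"criterion {self.name!r}: spread must be positive or "
                    f"'auto', got {self.spread!r}"
                )


class DecisionMatrix:
    """Performance table: one row per alternative, one column per criterion.

    Units are per criterion (percentages for metric columns, 0-1 codes for
    qualitative columns, raw negated log-loss values for the log-loss
    column); the auto-spread rule makes flows invariant to each column's
    scale choice.
    """

    def __init__(self, alternatives: Sequence[str],
                 criteria: Sequence[Criterion],
                 values: np.ndarray | Sequence[Sequence[float]]) -> None:
        self.alternatives = list(alternatives)
        self.criteria = list(criteria)
        self.values = np.asarray(values, dtype=float)
        n, m = len(self.alternatives), len(self.criteria)
        if n < 2:
            raise ValueError("a decision matrix requires at least two alternatives")
        if m < 1:
            raise ValueError("a decision matrix requires at least one criterion")
        if len(set(self.alternatives)) != n:
            raise ValueError("alternative names must be unique")
        if len({c.name for c in self.criteria}) != m:
            raise ValueError("criterion names must be unique")
        if self.values.shape != (n, m):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{n} alternatives x {m} criteria"
            )
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"missing or non-finite entry at alternative "
                f"{self.alternatives[bad[0]]!r}, criterion "
                f"{self.criteria[bad[1]].name!r}"
            )

    # -- lookups -----------------------------------------------------------
    def alt_index(self, alternative: str) -> int:
        try:
            return self.alternatives.index(alternative)
        except ValueError:
            raise KeyError(
                f"unknown alternative {alternative!r}; "
                f"known: {self.alternatives}"
            ) from None

    def crit_index(self, criterion: str) -> int:
        for i, c in enumerate(self.criteria):
            if c.name == criterion:
                return i
        raise KeyError(
            f"unknown criterion {criterion!r}; "
            f"known: {[c.name for c in self.criteria]}"
        )

    @property
    def criterion_names(self) -> list[str]:
        return [c.name for c in self.criteria]

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.criteria], float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.alternatives, name="alternative"),
                            columns=self.criterion_names)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (f"DecisionMatrix({len(self.alternatives)} alternatives x "
                f"{len(self.criteria)} criteria)")


@dataclass
class FlowTable:
    """Outranking flows plus their per-criterion decomposition.

    ``unicriterion[i, j]`` is phi_j(a_i); ``contributions()`` returns
    w_j * phi_j(a_i), the rainbow-bar segments, which sum across j to
    ``phi_net`` for every alternative.
    """

    alternatives: list[str]
    criterion_names: list[str]
    weights: np.ndarray
    spreads: np.ndarray
    phi_plus: np.ndarray
    phi_minus: np.ndarray
    phi_net: np.ndarray
    unicriterion: np.ndarray  # shape (n_alternatives, n_criteria)

    def contributions(self) -> pd.DataFrame:
        contrib = self.unicriterion * self.weights[np.newaxis, :]
        return pd.DataFrame(contrib,
                            index=pd.Index(self.alternatives, name="alternative"),
                            columns=self.criterion_names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"phi_plus": self.phi_plus, "phi_minus": self.phi_minus,
             "phi_net": self.phi_net},
            index=pd.Index(self.alternatives, name="alternative"))

    def ranking(self) -> pd.DataFrame:
        return rank_complete(self)


def deviation(matrix: DecisionMatrix, a: str, b: str, j: str) -> float:
    """Directed pairwise deviation of ``a`` over ``b`` on criterion ``j``:
    g_j(a) - g_j(b) for maximize criteria, g_j(b) - g_j(a) for minimize."""
    ia, ib = matrix.alt_index(a), matrix.alt_index(b)
    ij = matrix.crit_index(j)
    d = matrix.values[ia, ij] - matrix.values[ib, ij]
    if matrix.criteria[ij].direction == MINIMIZE:
        d = -d
    return float(d)


def gaussian_preference(d, s: float):
    """Gaussian preference degree: 0 for d <= 0, else 1 - exp(-d^2/(2 s^2)).

    Accepts scalars or arrays; the result lies in [0, 1).
    """
    if not np.isfinite(s) or s <= 0:
        raise ValueError(f"Gaussian preference spread must be positive, got {s!r}")
    d = np.asarray(d, dtype=float)
    pref = np.where(d > 0, -np.expm1(-np.square(d) / (2.0 * s * s)), 0.0)
    return float(pref) if pref.ndim == 0 else pref


def _validated_weights(matrix: DecisionMatrix,
                       weights: Sequence[float] | None) -> np.ndarray:
    w = matrix.weights if weights is None else np.asarray(weights, float)
    if w.shape != (len(matrix.criteria),):
        raise ValueError(
            f"weight vector length {w.shape} does not match "
            f"{len(matrix.criteria)} criteria"
        )
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if abs(w.sum() - 1.0) > _WEIGHT_SUM_TOL:
        raise ValueError(
            f"weights must sum to 1 (got {w.sum():.6g}); normalize first"
        )
    return w


def resolve_spreads(matrix: DecisionMatrix) -> np.ndarray:
    """Concrete Gaussian spread per criterion.

    ``"auto"`` spreads default to the population standard deviation of the
    criterion's column, falling back to half the column range when the
    standard deviation vanishes. A column with identical values carries no
    preference information at any spread; requesting an auto spread there
    with a positive weight is a configuration error (the criterion is inert).
    """
    spreads = np.empty(len(matrix.criteria))
    for j, crit in enumerate(matrix.criteria):
        if crit.spread != "auto":
            spreads[j] = float(crit.spread)
            continue
        col = matrix.values[:, j]
        s = float(np.std(col))  # population std (ddof=0)
        if s == 0.0:
            s = float(np.ptp(col)) / 2.0
        if s == 0.0:
            if crit.weight > 0:
                raise ValueError(
                    f"criterion {crit.name!r} has identical values for every "
                    "alternative, so no auto spread exists; drop it, give it "
                    "weight 0, or set an explicit spread"
                )
            s = 1.0  # weight 0: value is irrelevant
        spreads[j] = s
    logger.info("Gaussian spreads in use: %s",
                {c.name: round(s, 6) for c, s in zip(matrix.criteria, spreads)})
    return spreads


def _preference_cube(matrix: DecisionMatrix, spreads: np.ndarray) -> np.ndarray:
    """P[j, i_a, i_b] = P_j(a, b) for all ordered pairs; diagonal 0."""
    n, m = matrix.values.shape
    P = np.empty((m, n, n))
    for j, crit in enumerate(matrix.criteria):
        col = matrix.values[:, j]
        d = col[:, None] - col[None, :]
        if crit.direction == MINIMIZE:
            d = -d
        P[j] = gaussian_preference(d, spreads[j])
    return P


def preference_index(matrix: DecisionMatrix,
                     weights: Sequence[float] | None,
                     a: str, b: str,
                     spreads: Sequence[float] | None = None) -> float:
    """Aggregated preference pi(a, b) = sum_j w_j P_j(deviation(a, b, j))."""
    w = _validated_weights(matrix, weights)
    s = np.asarray(spreads, float) if spreads is not None else resolve_spreads(matrix)
    pi = 0.0
    for j, crit in enumerate(matrix.criteria):
        pi += w[j] * gaussian_preference(deviation(matrix, a, b, crit.name), s[j])
    return float(pi)


def compute_flows(matrix: DecisionMatrix,
                  weights: Sequence[float] | None = None) -> FlowTable:
    """Positive/negative/net outranking flows and unicriterion net flows.

    Flows are normalized by (n - 1), the standard PROMETHEE convention, so
    Phi+ and Phi- lie in [0, 1] and Phi in [-1, 1]; net flows sum to zero
    over alternatives.
    """
    n = len(matrix.alternatives)
    if n < 2:
        raise ValueError("ranking requires at least two alternatives")
    w = _validated_weights(matrix, weights)
    spreads = resolve_spreads(matrix)
    P = _preference_cube(matrix, spreads)

    pi = np.tensordot(w, P, axes=1)          # (n, n) aggregated indices
    phi_plus = pi.sum(axis=1) / (n - 1)
    phi_minus = pi.sum(axis=0) / (n - 1)
    uni = (P - P.transpose(0, 2, 1)).sum(axis=2).T / (n - 1)  # (n, m)

    return FlowTable(
        alternatives=list(matrix.alternatives),
        criterion_names=matrix.criterion_names,
        weights=w,
        spreads=spreads,
        phi_plus=phi_plus,
        phi_minus=phi_minus,
        phi_net=phi_plus - phi_minus,
        unicriterion=uni,
    )


def rank_complete(flows: FlowTable) -> pd.DataFrame:
    """Complete ranking by descending net flow.

    Ties are broken deterministically by alternative name (ascending).
    Returns a frame with columns rank, alternative, phi_plus, phi_minus,
    phi_net, ranks 1..n.
    """
    order = sorted(range(len(flows.alternatives)),
                   key=lambda i: (-flows.phi_net[i], flows.alternatives[i]))
    return pd.DataFrame({
        "rank": np.arange(1, len(order) + 1),
        "alternative": [flows.alternatives[i] for i in order],
        "phi_plus": flows.phi_plus[order],
        "phi_minus": flows.phi_minus[order],
        "phi_net": flows.phi_net[order],
    })
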