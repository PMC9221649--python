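"""Readers and writers for decision matrices, criteria configs and flow reports.

Formats are deliberately plain: CSV for tables (decision matrices with an
``alternative`` first column; ranking and contribution tables with 4-decimal
fixed formatting) and JSON for configuration and for a machine-precision
twin of every flow report.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .decision_matrix import criteria_from_config, encode_qualitative
from .promethee import Criterion, DecisionMatrix, FlowTable, rank_complete

__all__ = [
    "read_decision_matrix",
    "write_decision_matrix",
    "read_criteria_config",
    "write_flow_report",
    "read_flow_table",
]

_DECOMPOSITION_TOL = 1e-10


def read_criteria_config(path: str | Path) -> list[Criterion]:
    """Load a criteria config JSON: a list of objects with ``name``,
    ``direction``, ``weight_label`` or ``weight_value``, and ``spread``."""
    entries = json.loads(Path(path).read_text())
    if not isinstance(entries, list):
        raise ValueError(f"{path}: criteria config must be a JSON list")
    return criteria_from_config(entries)


def read_decision_matrix(path: str | Path,
                         criteria: Sequence[Criterion] | None = None,
                         ) -> DecisionMatrix:
    """Parse a decision-matrix CSV.

    The first column must be named ``alternative``; every other header is a
    criterion name. YES/NO literals are coded 1/0; numeric cells pass
    through. When ``criteria`` is given, each CSV column is matched to a
    configured criterion by name (all must be present) and the CSV column
    order is preserved; otherwise all criteria default to maximize with
    equal weights and auto spreads.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, skipinitialspace=True)
    if frame.columns[0] != "alternative":
        raise ValueError(
            f"{path}: first column must be 'alternative', got "
            f"{frame.columns[0]!r}"
        )
    names = frame["alternative"].tolist()
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"{path}: duplicate alternative names {dupes}")
    crit_names = list(frame.columns[1:])
    if not crit_names:
        raise ValueError(f"{path}: no criterion columns found")

    values = np.empty((len(names), len(crit_names)))
    for j, col in enumerate(crit_names):
        for i, cell in enumerate(frame[col]):
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) \
                    or (isinstance(cell, str) and not cell.strip()):
                raise ValueError(
                    f"{path}: missing value at row {names[i]!r}, "
                    f"column {col!r}"
                )
            try:
                values[i, j] = float(cell)
            except ValueError:
                try:
                    values[i, j] = encode_qualitative(cell)
                except ValueError as exc:
                    raise ValueError(
                        f"{path}: row {names[i]!r}, column {col!r}: {exc}"
                    ) from None

    if criteria is None:
        crits = [Criterion(name=c, weight=1.0 / len(crit_names))
                 for c in crit_names]
    else:
        by_name = {c.name: c for c in criteria}
        missing = [c for c in crit_names if c not in by_name]
        if missing:
            raise ValueError(
                f"{path}: columns {missing} are not in the criteria config")
        crits = [by_name[c] for c in crit_names]
    return DecisionMatrix(names, crits, values)


def write_decision_matrix(matrix: DecisionMatrix, path: str | Path,
                          decimals: int = 4) -> Path:
    path = Path(path)
    frame = matrix.to_frame().round(decimals)
    frame.to_csv(path, float_format=f"%.{decimals}f")
    return path


def write_flow_report(flows: FlowTable, out_dir: str | Path) -> dict[str, Path]:
    """Write the ranking table, the per-criterion contribution table, and a
    full-precision JSON twin.

    ``ranking.csv``: rank, alternative, phi_plus, phi_minus, phi_net
    (4 decimals). ``contributions.csv``: one row per alternative, one
    ``contrib_<criterion>`` column holding w_j * phi_j(a) — the rainbow-bar
    segments — whose row sums equal phi_net. The decomposition identity is
    re-checked before anything is written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    contrib = flows.contributions()
    residual = np.abs(contrib.sum(axis=1).to_numpy() - flows.phi_net)
    if residual.max() > _DECOMPOSITION_TOL:
        raise ValueError(
            "flow decomposition violated: contributions do not sum to the "
            f"net flow (max residual {residual.max():.3g})"
        )

    ranking_path = out_dir / "ranking.csv"
    ranking = rank_complete(flows)
    ranking.to_csv(ranking_path, index=False, float_format="%.4f")

    contrib_path = out_dir / "contributions.csv"
    contrib_out = contrib.rename(columns=lambda c: f"contrib_{c}")
    contrib_out.insert(0, "phi_net", flows.phi_net)
    contrib_out.to_csv(contrib_path, float_format="%.4f")

    json_path = out_dir / "flows.json"
    payload = {
        "alternatives": flows.alternatives,
        "criteria": flows.criterion_names,
        "weights": flows.weights.tolist(),
        "spreads": flows.spreads.tolist(),
        "phi_plus": flows.phi_plus.tolist(),
        "phi_minus": flows.phi_minus.tolist(),
        "phi_net": flows.phi_net.tolist(),
        "unicriterion": flows.unicriterion.tolist(),
    }
    json_path.write_text(json.dumps(payload, indent=2) + "\n")
    return {"ranking": ranking_path, "contributions": contrib_path,
            "json": json_path}


def read_flow_table(path: str | Path) -> FlowTable:
    """Rebuild a FlowTable from its machine-precision JSON twin."""
    payload = json.loads(Path(path).read_text())
    return FlowTable(
        alternatives=list(payload["alternatives"]),
        criterion_names=list(payload["criteria"]),
        weights=np.asarray(payload["weights"], float),
        spreads=np.asarray(payload["spreads"], float),
        phi_plus=np.asarray(payload["phi_plus"], float),
        phi_minus=np.asarray(payload["phi_minus"], float),
        phi_net=np.asarray(payload["phi_net"], float),
        unicriterion=np.asarray(payload["unicriterion"], float),
    )
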