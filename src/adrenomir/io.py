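"""Reading and writing the pipeline's tabular file formats.

All files are plain UTF-8 CSV with "." decimals. The Ct table is long-form
(one well per row); the expression matrix is wide (samples x markers, empty
cell = masked); the performance report mirrors the diagnostic-table layout
(one panel per row, percentages to two decimals).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import CT_COLUMNS, CtTable, ExpressionMatrix, GroupLabel

__all__ = [
    "read_ct_table",
    "write_ct_table",
    "read_expression_matrix",
    "write_expression_matrix",
    "write_report",
    "read_truth",
    "write_truth",
]

#: Cell contents treated as an undetermined well (case-insensitive).
MISSING_MARKERS = {"undetermined", "na", ""}


def _parse_ct(cell) -> float:
    if isinstance(cell, float) and np.isnan(cell):
        return np.nan
    text = str(cell).strip()
    if text.lower() in MISSING_MARKERS:
        return np.nan
    try:
        return float(text)
    except ValueError as exc:
        raise ValueError(f"unparseable Ct cell {cell!r}") from exc


def read_ct_table(path, config=None) -> CtTable:
    """Read a long-form Ct CSV and validate it.

    The header must name sample_id, group, assay, replicate and ct. The cell
    values "Undetermined", "NA" and the empty string (any case) map to the
    missing marker; everything else must parse as decimal cycles.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    lacking = [c for c in CT_COLUMNS if c not in df.columns]
    if lacking:
        raise ValueError(f"Ct table {path} missing columns {lacking}")
    df["ct"] = [_parse_ct(c) for c in df["ct"]]
    df["replicate"] = df["replicate"].astype(int)
    kwargs = {}
    if config is not None:
        kwargs = {"control_assays": tuple(config.control_assays), "ct_max": config.ct_max}
    return CtTable(data=df, **kwargs)


def write_ct_table(table: CtTable, path) -> None:
    df = table.data.copy()
    df["ct"] = [("Undetermined" if np.isnan(v) else format(v, ".4f")) for v in df["ct"]]
    df.to_csv(path, index=False)


def read_expression_matrix(path) -> ExpressionMatrix:
    """Read a wide expression CSV (rows = samples, columns = markers).

    Expects a ``sample_id`` index column and a ``group`` column; an optional
    ``control_ref`` column restores the per-sample reference Ct.
    """
    df = pd.read_csv(path, index_col="sample_id")
    if "group" not in df.columns:
        raise ValueError(f"expression matrix {path} lacks a 'group' column")
    groups = df.pop("group")
    control_ref = df.pop("control_ref") if "control_ref" in df.columns else None
    return ExpressionMatrix(values=df, groups=groups, control_ref=control_ref)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    df = matrix.values.copy()
    out = pd.DataFrame(index=df.index)
    out.index.name = "sample_id"
    out["group"] = matrix.groups
    if matrix.control_ref is not None:
        out["control_ref"] = matrix.control_ref.map(lambda v: format(v, ".6f"))
    for col in df.columns:
        out[col] = df[col].map(lambda v: "" if np.isnan(v) else format(v, ".6f"))
    out.to_csv(path)


def _pct(x) -> str:
    return "NA" if x is None else f"{100.0 * x:.2f}%"


def write_report(rows: Sequence, path) -> None:
    """Write the diagnostic-performance report CSV.

    ``rows`` is a non-empty sequence of (panel, ConfusionMetrics, ROCCurve)
    triples; one output row per panel with sensitivity, specificity, AUC, NPV
    and PPV as two-decimal percentages, plus the indeterminate-call count.
    """
    if not rows:
        raise ValueError("write_report requires at least one panel row")
    records = []
    for panel, confusion, roc in rows:
        label = panel.label if hasattr(panel, "label") else str(panel)
        records.append(
            {
                "model": label,
                "sensitivity": _pct(confusion.sensitivity),
                "specificity": _pct(confusion.specificity),
                "auc": _pct(roc.auc if roc is not None else None),
                "npv": _pct(confusion.npv),
                "ppv": _pct(confusion.ppv),
                "indeterminate": confusion.n_indeterminate,
            }
        )
    pd.DataFrame.from_records(records).to_csv(path, index=False)


def read_truth(path) -> dict:
    df = pd.read_csv(path, dtype=str)
    if not {"sample_id", "group"} <= set(df.columns):
        raise ValueError(f"truth table {path} needs sample_id and group columns")
    return {
        row.sample_id: GroupLabel.validate(row.group) for row in df.itertuples()
    }


def write_truth(truth: Mapping[str, str], path) -> None:
    df = pd.DataFrame(
        {"sample_id": list(truth.keys()), "group": list(truth.values())}
    ).sort_values("sample_id")
    df.to_csv(path, index=False)
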