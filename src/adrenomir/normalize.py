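"""Replicate aggregation and delta-Ct normalization.

Expression is quantified by the delta-Ct method against the combined
intrinsic (RNU48) and extrinsic spike-in (cel-miR-39) controls: per sample
the reference is the geometric mean of the two control Ct values, and a
target's stored value is -(Ct_target - reference), i.e. log2 relative
expression with higher values meaning more transcript.

Two details the instrument forces on the analysis are handled here. First,
triplicate wells are aggregated (mean by default) over the wells that did
amplify; a summary is missing only when every replicate is undetermined.
Second, markers with unmeasurable summaries are handled by the missing
policy: ``omit_feature`` drops such a marker from the analysis set entirely
(the study's rule for down-regulated markers that fail to amplify), while
``censor_fill`` substitutes expression at the detection floor.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .containers import CtTable, ExpressionMatrix

__all__ = [
    "aggregate_replicates",
    "normalize_delta_ct",
    "apply_missing_policy",
    "DeltaCtNormalizer",
]


def aggregate_replicates(table: CtTable, policy: str = "mean") -> pd.DataFrame:
    """Collapse replicate wells to one summary Ct per (sample, assay).

    Returns a samples x assays DataFrame of cycles with NaN where all
    replicates were undetermined.
    """
    if policy not in ("mean", "median"):
        raise ValueError("replicate policy must be 'mean' or 'median'")
    agg = {"mean": np.nanmean, "median": np.nanmedian}[policy]
    pivot = table.data.pivot_table(
        index="sample_id",
        columns="assay",
        values="ct",
        aggfunc=lambda v: np.nan if np.all(np.isnan(v)) else agg(v),
        dropna=False,
    )
    return pivot.sort_index()


def _control_reference(summary: pd.DataFrame, control_assays: Sequence[str],
                       control_mean: str) -> pd.Series:
    ctrl = summary.loc[:, list(control_assays)]
    bad = ctrl.isna().any(axis=1)
    if bad.any():
        raise ValueError(
            f"sample {bad.index[bad.argmax()]} lacks a measurable control Ct; "
            "delta-Ct normalization is undefined"
        )
    if control_mean == "geometric":
        return np.exp(np.log(ctrl).mean(axis=1))
    if control_mean == "arithmetic":
        return ctrl.mean(axis=1)
    raise ValueError("control_mean must be 'geometric' or 'arithmetic'")


def normalize_delta_ct(
    summary: pd.DataFrame,
    control_assays: Sequence[str] = ("RNU48", "cel-miR-39"),
    groups: pd.Series = None,
    control_mean: str = "geometric",
) -> ExpressionMatrix:
    """Delta-Ct normalize a summary Ct table against the controls.

    value(s, a) = -(Ct(s, a) - control_ref(s)) with control_ref(s) the
    geometric mean of the sample's control Cts (arithmetic available by
    config). Control columns are removed from the output.
    """
    absent = [c for c in control_assays if c not in summary.columns]
    if absent:
        raise ValueError(f"control assays {absent} not present in summary table")
    ref = _control_reference(summary, control_assays, control_mean)
    targets = [c for c in summary.columns if c not in set(control_assays)]
    values = -(summary.loc[:, targets].sub(ref, axis=0))
    if groups is None:
        groups = pd.Series("UNKNOWN", index=summary.index)
    return ExpressionMatrix(values=values, groups=groups, control_ref=ref)


def apply_missing_policy(
    matrix: ExpressionMatrix,
    policy: str = "omit_feature",
    ct_max: float = 40.0,
) -> ExpressionMatrix:
    """Resolve masked expression values.

    omit_feature: drop every marker with at least one masked value in the
    analysis set. censor_fill: replace masked values with expression at the
    detection floor, -(ct_max - control_ref).
    """
    if policy == "omit_feature":
        keep = [c for c in matrix.values.columns if not matrix.values[c].isna().any()]
        return ExpressionMatrix(
            values=matrix.values.loc[:, keep].copy(),
            groups=matrix.groups.copy(),
            control_ref=None if matrix.control_ref is None else matrix.control_ref.copy(),
        )
    if policy == "censor_fill":
        if not matrix.values.isna().any().any():
            return ExpressionMatrix(
                values=matrix.values.copy(), groups=matrix.groups.copy(),
                control_ref=None if matrix.control_ref is None else matrix.control_ref.copy(),
            )
        if matrix.control_ref is None:
            raise ValueError("censor_fill requires the per-sample control reference")
        values = matrix.values.copy()
        floor = -(ct_max - matrix.control_ref)
        for col in values.columns:
            mask = values[col].isna()
            values.loc[mask, col] = floor[mask]
        return ExpressionMatrix(
            values=values, groups=matrix.groups.copy(),
            control_ref=matrix.control_ref.copy(),
        )
    raise ValueError("missing policy must be 'omit_feature' or 'censor_fill'")


class DeltaCtNormalizer:
    """Transformer from a raw CtTable to an ExpressionMatrix.

    Composes replicate aggregation, delta-Ct normalization against the two
    controls, and the missing-value policy. Stateless between calls, so
    ``transform`` alone is the whole contract; fit is a no-op kept for
    pipeline compatibility.
    """

    def __init__(
        self,
        control_assays: Sequence[str] = ("RNU48", "cel-miR-39"),
        replicate_policy: str = "mean",
        missing_policy: str = "omit_feature",
        control_mean: str = "geometric",
        ct_max: float = 40.0,
    ) -> None:
        self.control_assays = tuple(control_assays)
        self.replicate_policy = replicate_policy
        self.missing_policy = missing_policy
        self.control_mean = control_mean
        self.ct_max = ct_max

    def get_params(self, deep: bool = True) -> dict:
        return {
            "control_assays": self.control_assays,
            "replicate_policy": self.replicate_policy,
            "missing_policy": self.missing_policy,
            "control_mean": self.control_mean,
            "ct_max": self.ct_max,
        }

    def set_params(self, **params) -> "DeltaCtNormalizer":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    def fit(self, table: CtTable, y=None) -> "DeltaCtNormalizer":
        return self

    def transform(self, table: CtTable) -> ExpressionMatrix:
        summary = aggregate_replicates(table, self.replicate_policy)
        matrix = normalize_delta_ct(
            summary,
            control_assays=self.control_assays,
            groups=table.groups,
            control_mean=self.control_mean,
        )
        return apply_missing_policy(matrix, self.missing_policy, self.ct_max)

    def fit_transform(self, table: CtTable, y=None) -> ExpressionMatrix:
        return self.fit(table).transform(table)
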