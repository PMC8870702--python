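"""In-memory containers: raw Ct tables and normalized expression matrices."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["GroupLabel", "INDETERMINATE", "CtTable", "ExpressionMatrix"]


class GroupLabel:
    """The four admissible sample-group labels.

    ACA: adrenocortical adenoma (benign); ACC: adrenocortical carcinoma
    (malignant); NAC: normal adrenal cortex; UNKNOWN: blinded validation
    sample awaiting classification.
    """

    ACA = "ACA"
    ACC = "ACC"
    NAC = "NAC"
    UNKNOWN = "UNKNOWN"
    ALL = (ACA, ACC, NAC, UNKNOWN)

    @classmethod
    def validate(cls, value: str) -> str:
        if value not in cls.ALL:
            raise ValueError(
                f"unknown group label {value!r}; expected one of {cls.ALL}"
            )
        return value


#: Final-call marker for an unknown sample with no strict vote majority.
INDETERMINATE = "INDETERMINATE"

CT_COLUMNS = ("sample_id", "group", "assay", "replicate", "ct")


@dataclass
class CtTable:
    """Long-form raw qPCR measurements.

    ``data`` holds one row per well with columns sample_id, group, assay,
    replicate and ct (float cycles; NaN marks an undetermined well). Each
    sample must carry wells for every control assay, and the
    (sample_id, assay, replicate) triple is unique.
    """

    data: pd.DataFrame
    control_assays: tuple = ("RNU48", "cel-miR-39")
    ct_max: float = 40.0

    def __post_init__(self) -> None:
        df = self.data
        missing_cols = [c for c in CT_COLUMNS if c not in df.columns]
        if missing_cols:
            raise ValueError(f"CtTable missing columns: {missing_cols}")
        df = df.loc[:, list(CT_COLUMNS)].reset_index(drop=True)
        df["replicate"] = df["replicate"].astype(int)
        df["ct"] = df["ct"].astype(float)
        for g in df["group"].unique():
            GroupLabel.validate(g)
        if (df["replicate"] < 1).any():
            raise ValueError("replicate indices must be positive")
        dup = df.duplicated(subset=["sample_id", "assay", "replicate"])
        if dup.any():
            first = df.loc[dup, ["sample_id", "assay", "replicate"]].iloc[0]
            raise ValueError(
                "duplicate measurement for "
                f"({first.sample_id}, {first.assay}, {first.replicate})"
            )
        observed = df["ct"].dropna()
        if ((observed <= 0) | (observed > self.ct_max)).any():
            bad = observed[(observed <= 0) | (observed > self.ct_max)].iloc[0]
            raise ValueError(
                f"ct value {bad} outside the admissible range (0, {self.ct_max}]"
            )
        assays_by_sample = df.groupby("sample_id")["assay"].agg(set)
        for sample_id, assays in assays_by_sample.items():
            lacking = [c for c in self.control_assays if c not in assays]
            if lacking:
                raise ValueError(
                    f"sample {sample_id} has no wells for control(s) {lacking}"
                )
        self.data = df

    @property
    def sample_ids(self) -> list:
        return sorted(self.data["sample_id"].unique())

    @property
    def assay_ids(self) -> list:
        return sorted(self.data["assay"].unique())

    @property
    def groups(self) -> pd.Series:
        g = self.data.drop_duplicates("sample_id").set_index("sample_id")["group"]
        return g.sort_index()

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class ExpressionMatrix:
    """Samples x markers matrix of log2 relative expression (-dCt).

    Values are -(Ct_target - control_ref) so that larger numbers mean higher
    expression; NaN entries are masked (unmeasurable wells). Control assays
    never appear among the columns; ``control_ref`` keeps each sample's
    per-sample reference Ct for detection-floor fills.
    """

    values: pd.DataFrame
    groups: pd.Series
    control_ref: pd.Series = None

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        missing = [s for s in self.values.index if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without group labels: {missing}")
        self.groups = self.groups.loc[self.values.index]
        for g in self.groups.unique():
            GroupLabel.validate(g)
        if self.control_ref is not None:
            self.control_ref = self.control_ref.loc[self.values.index].astype(float)

    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    @property
    def assay_ids(self) -> list:
        return list(self.values.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values.loc[list(sample_ids)].copy(),
            groups=self.groups.loc[list(sample_ids)].copy(),
            control_ref=None if self.control_ref is None
            else self.control_ref.loc[list(sample_ids)].copy(),
        )

    def restrict_groups(self, groups: Iterable[str]) -> "ExpressionMatrix":
        keep = [s for s in self.sample_ids if self.groups[s] in set(groups)]
        return self.subset_samples(keep)

    def feature_array(self, assays: Sequence[str]) -> np.ndarray:
        """Dense feature block for the given markers; raises on masked cells."""
        absent = [a for a in assays if a not in self.values.columns]
        if absent:
            raise KeyError(f"markers not present in matrix: {absent}")
        block = self.values.loc[:, list(assays)]
        if block.isna().any().any():
            bad = block.isna().stack()
            sample, assay = bad[bad].index[0]
            raise ValueError(
                f"masked expression value for sample {sample}, marker {assay}"
            )
        return block.to_numpy(dtype=float)
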