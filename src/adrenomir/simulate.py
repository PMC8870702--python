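"""Synthetic RT-qPCR Ct data with the study's statistical structure.

The generator emulates a two-cohort adrenocortical tumor design: a discovery
cohort of 10 adenomas (ACA), 10 carcinomas (ACC) and 10 normal cortices
(NAC), and a blinded validation cohort of 22 ACA and 21 ACC samples. Sixteen
literature-selected miRNA assays are measured in triplicate together with an
intrinsic reference (RNU48) and an extrinsic spike-in (cel-miR-39).

Group effects act on the Ct scale under the qPCR doubling assumption: one
cycle equals one log2 expression unit, so a marker up-regulated in ACC by
``effect_log2`` cycles has its ACC Ct lowered by that amount. Replicate
wells whose Ct exceeds the censoring threshold are reported as undetermined,
which is how low-abundance down-regulated markers drop out of real runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .containers import CtTable, GroupLabel
from .seeding import child_seed

__all__ = [
    "AssaySpec",
    "SyntheticSpec",
    "default_spec",
    "spec_with_marker_effects",
    "generate_cohort",
    "TARGET_DIRECTIONS",
    "CONTROL_ASSAYS",
]

UP = "up_in_ACC"
DOWN = "down_in_ACC"
CONTROL = "control"

#: The 16 literature-selected target assays and their expression direction in
#: carcinoma relative to adenoma.
TARGET_DIRECTIONS: Tuple[Tuple[str, str], ...] = (
    ("hsa-miR-7", DOWN),
    ("hsa-miR-9", UP),
    ("hsa-miR-21", UP),
    ("hsa-miR-195", DOWN),
    ("hsa-miR-205", DOWN),
    ("hsa-miR-210", UP),
    ("hsa-miR-214", DOWN),
    ("hsa-miR-335", DOWN),
    ("hsa-miR-375", DOWN),
    ("hsa-miR-431", DOWN),
    ("hsa-miR-483-3p", UP),
    ("hsa-miR-483-5p", UP),
    ("hsa-miR-497", DOWN),
    ("hsa-miR-503", UP),
    ("hsa-miR-508", UP),
    ("hsa-miR-511", DOWN),
)

CONTROL_ASSAYS: Tuple[str, ...] = ("RNU48", "cel-miR-39")

_SIGN = {UP: 1.0, DOWN: -1.0, CONTROL: 0.0}


@dataclass(frozen=True)
class AssaySpec:
    name: str
    direction: str

    def __post_init__(self) -> None:
        if self.direction not in (UP, DOWN, CONTROL):
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the Ct generator.

    effect_log2 maps assay -> magnitude (log2 units == cycles) of the ACC
    shift relative to ACA, applied with the sign of the assay's direction.
    aca_vs_nac_log2 maps assay -> signed expression shift of ACA relative to
    NAC. Controls receive zero group effect by construction but keep a third
    of the biological variability so normalization is genuinely exercised.
    """

    assays: Tuple[AssaySpec, ...]
    baseline_ct: Mapping[str, float]
    effect_log2: Mapping[str, float]
    aca_vs_nac_log2: Mapping[str, float]
    replicate_sd: float = 0.25
    biological_sd: float = 0.75
    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"ACA": 10, "ACC": 10, "NAC": 10}
    )
    n_validation: Mapping[str, int] = field(
        default_factory=lambda: {"ACA": 22, "ACC": 21}
    )
    n_replicates: int = 3
    censor_above: float = 38.0
    ct_max: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicate_sd < 0 or self.biological_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.censor_above > self.ct_max:
            raise ValueError("censor_above must not exceed ct_max")
        names = [a.name for a in self.assays]
        if len(set(names)) != len(names):
            raise ValueError("assay names must be unique")
        for name in names:
            if name not in self.baseline_ct:
                raise ValueError(f"no baseline Ct for assay {name}")
        for a in self.assays:
            if a.direction == CONTROL and self.effect_log2.get(a.name, 0.0) != 0.0:
                raise ValueError(f"control assay {a.name} must have zero effect")

    @property
    def assay_names(self) -> list:
        return [a.name for a in self.assays]

    @property
    def target_names(self) -> list:
        return [a.name for a in self.assays if a.direction != CONTROL]

    @property
    def control_names(self) -> list:
        return [a.name for a in self.assays if a.direction == CONTROL]

    def direction_of(self, name: str) -> str:
        for a in self.assays:
            if a.name == name:
                return a.direction
        raise KeyError(name)


def default_spec(
    effect_log2: float = 2.0,
    aca_vs_nac_log2: float = 1.0,
    replicate_sd: float = 0.25,
    biological_sd: float = 0.75,
    seed: int = 0,
) -> SyntheticSpec:
    """The study-design defaults.

    16 targets (directions as established by the literature), 2 controls,
    triplicate wells, discovery 10/10/10 and validation 22 ACA / 21 ACC.
    Target baselines sit at 30 cycles except the two lowest-abundance
    down-regulated markers (miR-7, miR-511) at 35, which places their
    down-regulated carcinoma wells near the 38-cycle censoring threshold.
    """
    assays = tuple(
        [AssaySpec(n, d) for n, d in TARGET_DIRECTIONS]
        + [AssaySpec(c, CONTROL) for c in CONTROL_ASSAYS]
    )
    baseline = {name: 30.0 for name, _ in TARGET_DIRECTIONS}
    baseline["hsa-miR-7"] = 35.0
    baseline["hsa-miR-511"] = 35.0
    baseline["RNU48"] = 22.0
    baseline["cel-miR-39"] = 24.0
    effects = {name: float(effect_log2) for name, _ in TARGET_DIRECTIONS}
    effects.update({c: 0.0 for c in CONTROL_ASSAYS})
    aca_shift = {
        name: _SIGN[d] * float(aca_vs_nac_log2) for name, d in TARGET_DIRECTIONS
    }
    aca_shift.update({c: 0.0 for c in CONTROL_ASSAYS})
    return SyntheticSpec(
        assays=assays,
        baseline_ct=baseline,
        effect_log2=effects,
        aca_vs_nac_log2=aca_shift,
        replicate_sd=replicate_sd,
        biological_sd=biological_sd,
        seed=seed,
    )


def spec_with_marker_effects(
    strong_markers: Sequence[str],
    strong_effect: float = 2.0,
    background_effect: float = 0.5,
    **kwargs,
) -> SyntheticSpec:
    """Default spec with a designated set of strong markers.

    The named markers carry ``strong_effect`` log2 units; the remaining
    targets carry ``background_effect`` (weaker literature evidence). The
    ACA-vs-NAC shift scales proportionally (half the carcinoma effect, as in
    the defaults), so the strong markers carry the largest effect in every
    group contrast.
    """
    spec = default_spec(**kwargs)
    effects = dict(spec.effect_log2)
    aca = dict(spec.aca_vs_nac_log2)
    for a in spec.assays:
        if a.direction == CONTROL:
            continue
        eff = float(strong_effect if a.name in set(strong_markers) else background_effect)
        effects[a.name] = eff
        aca[a.name] = _SIGN[a.direction] * 0.5 * eff
    unknown = set(strong_markers) - set(spec.target_names)
    if unknown:
        raise KeyError(f"not target assays: {sorted(unknown)}")
    return replace(spec, effect_log2=effects, aca_vs_nac_log2=aca)


def _group_expression_shift(spec: SyntheticSpec, group: str, assay: str) -> float:
    """Signed log2 expression shift of ``group`` relative to NAC."""
    direction = spec.direction_of(assay)
    if direction == CONTROL or group == GroupLabel.NAC:
        return 0.0
    aca = float(spec.aca_vs_nac_log2.get(assay, 0.0))
    if group == GroupLabel.ACA:
        return aca
    if group == GroupLabel.ACC:
        return aca + _SIGN[direction] * float(spec.effect_log2.get(assay, 0.0))
    raise ValueError(f"no expression model for group {group}")


def generate_cohort(
    spec: SyntheticSpec, cohort: str, seed: int = None
) -> Tuple[CtTable, Dict[str, str]]:
    """Generate one cohort's Ct table and its true labels.

    Discovery samples carry their group label in the table; validation
    samples are labeled UNKNOWN in the table, with the true ACA/ACC label
    returned only in the ``truth`` mapping. Identical (spec, cohort, seed)
    always produce an identical table.
    """
    if cohort not in ("discovery", "validation"):
        raise ValueError("cohort must be 'discovery' or 'validation'")
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(child_seed(seed, "simulate", cohort))

    if cohort == "discovery":
        plan = [("ACA", spec.n_per_group["ACA"]), ("ACC", spec.n_per_group["ACC"]),
                ("NAC", spec.n_per_group["NAC"])]
        samples = [
            (f"D-{g}-{i + 1:02d}", g, g) for g, n in plan for i in range(n)
        ]
    else:
        plan = [("ACA", spec.n_validation["ACA"]), ("ACC", spec.n_validation["ACC"])]
        samples = []
        counter = 0
        for g, n in plan:
            for _ in range(n):
                counter += 1
                samples.append((f"V{counter:02d}", GroupLabel.UNKNOWN, g))

    records = []
    for sample_id, table_group, true_group in samples:
        for assay in spec.assay_names:
            direction = spec.direction_of(assay)
            bio_sd = spec.biological_sd / 3.0 if direction == CONTROL else spec.biological_sd
            latent = (
                spec.baseline_ct[assay]
                - _group_expression_shift(spec, true_group, assay)
                + rng.normal(0.0, bio_sd)
            )
            for rep in range(1, spec.n_replicates + 1):
                ct = latent + rng.normal(0.0, spec.replicate_sd)
                if ct > spec.censor_above:
                    ct = np.nan
                elif ct <= 0:
                    ct = np.nan  # below-cycle-zero artifacts are unmeasurable
                records.append((sample_id, table_group, assay, rep, ct))

    df = pd.DataFrame.from_records(
        records, columns=["sample_id", "group", "assay", "replicate", "ct"]
    )
    table = CtTable(data=df, control_assays=tuple(spec.control_names) or CONTROL_ASSAYS,
                    ct_max=spec.ct_max)
    truth = {sample_id: true for sample_id, _, true in samples}
    return table, truth
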