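"""Run configuration for the panel pipeline.

Plain dataclasses with eager validation; a :class:`RunConfig` aggregates the
per-stage configurations and can round-trip through YAML for the command line.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from typing import Sequence

import yaml

__all__ = [
    "NNConfig",
    "SearchConfig",
    "VoteConfig",
    "RunConfig",
    "load_config",
    "dump_config",
]

GROUP_MODES = ("three_class", "two_class")
REPLICATE_POLICIES = ("mean", "median")
MISSING_POLICIES = ("omit_feature", "censor_fill")
CONTROL_MEANS = ("geometric", "arithmetic")
RESAMPLE_MODES = ("subsample_90", "full_refit")
CAPABILITY_MODES = ("mean_rep", "pooled")


@dataclass(frozen=True)
class NNConfig:
    """Single-hidden-layer network hyperparameters.

    hidden_units : width of the logistic hidden layer.
    weight_decay : L2 penalty on weight matrices (biases excluded).
    max_epochs : full-batch gradient-descent epochs (no early stopping).
    learning_rate : step size on the mean cross-entropy gradient.
    init_scale : weights start Uniform(-init_scale, init_scale).
    """

    hidden_units: int = 3
    weight_decay: float = 0.01
    max_epochs: int = 200
    learning_rate: float = 0.5
    init_scale: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.init_scale <= 0:
            raise ValueError("init_scale must be > 0")
        if self.seed < 0:
            raise ValueError("seed must be >= 0")


@dataclass(frozen=True)
class SearchConfig:
    """Repeated stratified learner-tester cross-validation settings.

    Defaults follow the study design: 1000 repetitions of a 90-10% split
    drawing 9 learners and 1 tester per group, panels of 2-4 markers,
    selection at >= 90% classification capability.
    """

    n_reps: int = 1000
    learners_per_group: int = 9
    testers_per_group: int = 1
    selection_threshold: float = 0.90
    group_mode: str = "three_class"
    min_size: int = 2
    max_size: int = 4
    capability_mode: str = "mean_rep"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.learners_per_group < 1 or self.testers_per_group < 1:
            raise ValueError("learners/testers per group must be >= 1")
        if not 0 < self.selection_threshold <= 1:
            raise ValueError("selection_threshold must be in (0, 1]")
        if self.group_mode not in GROUP_MODES:
            raise ValueError(f"group_mode must be one of {GROUP_MODES}")
        if self.min_size < 1 or self.min_size > self.max_size:
            raise ValueError("require 1 <= min_size <= max_size")
        if self.capability_mode not in CAPABILITY_MODES:
            raise ValueError(f"capability_mode must be one of {CAPABILITY_MODES}")
        if self.seed < 0:
            raise ValueError("seed must be >= 0")


@dataclass(frozen=True)
class VoteConfig:
    """Ensemble-vote classification settings for unknown samples.

    Each unknown is classified ``n_iterations`` times; the final call is the
    class taken in strictly more than ``majority_threshold`` of iterations,
    otherwise INDETERMINATE. ``subsample_90`` redraws a stratified 90% learner
    subset per iteration; ``full_refit`` retrains on all knowns with a fresh
    initialization only.
    """

    n_iterations: int = 10_000
    majority_threshold: float = 0.5
    resample_mode: str = "subsample_90"
    train_groups: tuple = ("ACA", "ACC")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not 0 <= self.majority_threshold < 1:
            raise ValueError("majority_threshold must be in [0, 1)")
        if self.resample_mode not in RESAMPLE_MODES:
            raise ValueError(f"resample_mode must be one of {RESAMPLE_MODES}")
        if len(self.train_groups) < 2:
            raise ValueError("need at least two training groups")
        if self.seed < 0:
            raise ValueError("seed must be >= 0")


@dataclass(frozen=True)
class RunConfig:
    """Top-level pipeline configuration shared by all stages."""

    control_assays: tuple = ("RNU48", "cel-miR-39")
    ct_max: float = 40.0
    replicate_policy: str = "mean"
    missing_policy: str = "omit_feature"
    control_mean: str = "geometric"
    nn: NNConfig = field(default_factory=NNConfig)
    search: SearchConfig = field(default_factory=SearchConfig)
    vote: VoteConfig = field(default_factory=VoteConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.control_assays) < 1:
            raise ValueError("at least one control assay is required")
        if self.ct_max <= 0:
            raise ValueError("ct_max must be > 0")
        if self.replicate_policy not in REPLICATE_POLICIES:
            raise ValueError(f"replicate_policy must be one of {REPLICATE_POLICIES}")
        if self.missing_policy not in MISSING_POLICIES:
            raise ValueError(f"missing_policy must be one of {MISSING_POLICIES}")
        if self.control_mean not in CONTROL_MEANS:
            raise ValueError(f"control_mean must be one of {CONTROL_MEANS}")
        if self.seed < 0:
            raise ValueError("seed must be >= 0")

    def with_seed(self, seed: int) -> "RunConfig":
        """Return a copy with the master seed (and stage seeds) replaced."""
        return replace(
            self,
            seed=seed,
            nn=replace(self.nn, seed=seed),
            search=replace(self.search, seed=seed),
            vote=replace(self.vote, seed=seed),
        )


def load_config(path) -> RunConfig:
    """Load a RunConfig from YAML; missing keys take their defaults."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    nn = NNConfig(**raw.pop("nn", {}))
    search = SearchConfig(**raw.pop("search", {}))
    vote_raw = raw.pop("vote", {})
    if "train_groups" in vote_raw:
        vote_raw["train_groups"] = tuple(vote_raw["train_groups"])
    vote = VoteConfig(**vote_raw)
    if "control_assays" in raw:
        raw["control_assays"] = tuple(raw["control_assays"])
    return RunConfig(nn=nn, search=search, vote=vote, **raw)


def dump_config(config: RunConfig, path) -> None:
    payload = asdict(config)
    payload["control_assays"] = list(config.control_assays)
    payload["vote"]["train_groups"] = list(config.vote.train_groups)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
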