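"""Combinatorial panel search by repeated learner-tester cross-validation.

Candidate panels of 2-4 markers are enumerated exhaustively and scored by
the discovery scheme: in each repetition a stratified 90-10% split draws 9
learners and 1 tester per group (9-9-9 / 1-1-1 for the three-class analysis,
9-9 / 1-1 for adenoma-vs-carcinoma alone), a fresh network is trained on the
learners restricted to the panel's markers, and the held-out testers are
classified. A panel's classification capability is its mean tester accuracy
over the repetitions (1000 by default), and panels at or above the selection
threshold (90% by default) go forward to validation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .config import NNConfig, SearchConfig
from .containers import ExpressionMatrix
from .neural import train_batched
from .seeding import child_seed

__all__ = [
    "PanelCombination",
    "CVResult",
    "enumerate_combinations",
    "cross_validate_combination",
    "select_models",
    "search_panels",
    "PanelSearchCV",
    "CANDIDATE_PANELS",
]


@dataclass(frozen=True)
class PanelCombination:
    """An ordered set of distinct marker names."""

    assays: Tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.assays) < 1:
            raise ValueError("a panel needs at least one marker")
        if len(set(self.assays)) != len(self.assays):
            raise ValueError(f"duplicate markers in panel {self.assays}")
        object.__setattr__(self, "assays", tuple(self.assays))

    @classmethod
    def from_label(cls, label: str) -> "PanelCombination":
        return cls(tuple(part.strip() for part in label.split("+")))

    @property
    def label(self) -> str:
        return " + ".join(self.assays)

    @property
    def key(self) -> Tuple[str, ...]:
        """Order-free identity of the panel."""
        return tuple(sorted(self.assays))

    def __len__(self) -> int:
        return len(self.assays)


#: The 24 published candidate combinations taken forward to validation,
#: keyed by their model number.
CANDIDATE_PANELS: Dict[int, PanelCombination] = {
    number: PanelCombination.from_label(label)
    for number, label in {
        1: "hsa-miR-9 + hsa-miR-375",
        2: "hsa-miR-9 + hsa-miR-503",
        3: "hsa-miR-375 + hsa-miR-503",
        4: "hsa-miR-210 + hsa-miR-503",
        5: "hsa-miR-375 + hsa-miR-497",
        6: "hsa-miR-483-3p + hsa-miR-503",
        7: "hsa-miR-503 + hsa-miR-508",
        8: "hsa-miR-195 + hsa-miR-503 + hsa-miR-508",
        9: "hsa-miR-195 + hsa-miR-210 + hsa-miR-503",
        10: "hsa-miR-9 + hsa-miR-195 + hsa-miR-503",
        11: "hsa-miR-9 + hsa-miR-210 + hsa-miR-503",
        12: "hsa-miR-9 + hsa-miR-375 + hsa-miR-503",
        13: "hsa-miR-9 + hsa-miR-483-3p + hsa-miR-503",
        14: "hsa-miR-9 + hsa-miR-497 + hsa-miR-503",
        15: "hsa-miR-195 + hsa-miR-375 + hsa-miR-497",
        16: "hsa-miR-210 + hsa-miR-375 + hsa-miR-503",
        17: "hsa-miR-210 + hsa-miR-483-5p + hsa-miR-503",
        18: "hsa-miR-375 + hsa-miR-503 + hsa-miR-508",
        19: "hsa-miR-375 + hsa-miR-483-3p + hsa-miR-503",
        20: "hsa-miR-9 + hsa-miR-195 + hsa-miR-375 + hsa-miR-503",
        21: "hsa-miR-9 + hsa-miR-210 + hsa-miR-483-5p + hsa-miR-503",
        22: "hsa-miR-210 + hsa-miR-375 + hsa-miR-503 + hsa-miR-508",
        23: "hsa-miR-375 + hsa-miR-483-5p + hsa-miR-503 + hsa-miR-508",
        24: "hsa-miR-375 + hsa-miR-497 + hsa-miR-503 + hsa-miR-508",
    }.items()
}


@dataclass
class CVResult:
    """A panel's repeated-split classification capability."""

    combination: PanelCombination
    capability: float
    per_rep_accuracies: np.ndarray

    def __post_init__(self) -> None:
        self.per_rep_accuracies = np.asarray(self.per_rep_accuracies, dtype=float)
        if not (0.0 <= self.capability <= 1.0):
            raise ValueError("capability must be a fraction in [0, 1]")


def enumerate_combinations(assays: Sequence[str], min_size: int,
                           max_size: int) -> List[PanelCombination]:
    """All marker subsets with min_size <= |S| <= max_size.

    Deterministic: sizes ascending, lexicographic order of sorted names
    within a size.
    """
    if min_size > max_size:
        raise ValueError("min_size must not exceed max_size")
    if max_size > len(assays):
        raise ValueError("max_size exceeds the number of markers")
    names = sorted(assays)
    out: List[PanelCombination] = []
    for size in range(min_size, max_size + 1):
        for combo in itertools.combinations(names, size):
            out.append(PanelCombination(combo))
    return out


def _mode_groups(group_mode: str) -> Tuple[str, ...]:
    return ("ACA", "ACC", "NAC") if group_mode == "three_class" else ("ACA", "ACC")


def cross_validate_combination(
    matrix: ExpressionMatrix,
    combo: PanelCombination,
    config: SearchConfig = None,
    nn: NNConfig = None,
) -> CVResult:
    """Score one panel by repeated stratified learner-tester splits.

    Each repetition draws ``learners_per_group`` samples per group without
    replacement, trains a fresh network (new split and new initialization via
    per-repetition child seeds of ``config.seed``), and classifies
    ``testers_per_group`` held-out samples per group.
    """
    config = config or SearchConfig()
    nn = nn or NNConfig()
    groups = _mode_groups(config.group_mode)
    sub = matrix.restrict_groups(groups)
    # canonical pre-sort by sample id so results do not depend on row order
    sub = sub.subset_samples(sorted(sub.sample_ids))
    X_all = sub.feature_array(combo.assays)
    y_all = sub.groups.to_numpy()

    l, t = config.learners_per_group, config.testers_per_group
    group_rows: Dict[str, np.ndarray] = {}
    for g in groups:
        rows = np.flatnonzero(y_all == g)
        if rows.size < l + t:
            raise ValueError(
                f"group {g} has {rows.size} samples; needs >= {l + t} "
                f"({l} learners + {t} testers)"
            )
        group_rows[g] = rows

    B = config.n_reps
    n_learn, n_test = l * len(groups), t * len(groups)
    learn_idx = np.empty((B, n_learn), dtype=int)
    test_idx = np.empty((B, n_test), dtype=int)
    init_seeds = np.empty(B, dtype=np.int64)
    for r in range(B):
        rng = np.random.default_rng(child_seed(config.seed, "split", r))
        lpos, tpos = 0, 0
        for g in groups:
            rows = group_rows[g]
            perm = rng.permutation(rows.size)
            learners = rows[perm[:l]]
            testers = rows[perm[l:l + t]]
            assert np.intersect1d(learners, testers).size == 0
            learn_idx[r, lpos:lpos + l] = learners
            test_idx[r, tpos:tpos + t] = testers
            lpos += l
            tpos += t
        init_seeds[r] = child_seed(config.seed, "init", r)

    classes = np.array(sorted(np.unique(y_all)))
    Y_learn = (y_all[learn_idx][:, :, None] == classes[None, None, :]).astype(float)
    nets = train_batched(X_all[learn_idx], Y_learn, classes, nn, init_seeds)
    pred = nets.predict(X_all[test_idx])          # (B, n_test)
    correct = pred == y_all[test_idx]
    per_rep = correct.mean(axis=1)
    if config.capability_mode == "pooled":
        capability = float(correct.mean())
    else:
        capability = float(per_rep.mean())
    return CVResult(combination=combo, capability=capability,
                    per_rep_accuracies=per_rep)


def select_models(results: Sequence[CVResult],
                  threshold: float = 0.90) -> List[PanelCombination]:
    """Panels at or above the capability threshold, best first.

    Ties in capability break lexicographically by panel label.
    """
    if not results:
        raise ValueError("select_models requires at least one CVResult")
    kept = [r for r in results if r.capability >= threshold]
    kept.sort(key=lambda r: (-r.capability, r.combination.label))
    return [r.combination for r in kept]


def search_panels(matrix: ExpressionMatrix, config: SearchConfig = None,
                  nn: NNConfig = None,
                  combinations: Sequence[PanelCombination] = None) -> List[CVResult]:
    """Cross-validate every candidate panel (exhaustive enumeration).

    All panels share the same repetition seeds, so their capabilities are
    paired over identical splits.
    """
    config = config or SearchConfig()
    if combinations is None:
        combinations = enumerate_combinations(
            matrix.assay_ids, config.min_size, config.max_size
        )
    return [cross_validate_combination(matrix, c, config, nn) for c in combinations]


class PanelSearchCV:
    """Meta-estimator running the combinatorial search on an expression matrix.

    After ``fit``, ``results_`` holds one CVResult per candidate panel and
    ``selected_`` the panels meeting the selection threshold.
    """

    def __init__(self, config: SearchConfig = None, nn: NNConfig = None,
                 combinations: Sequence[PanelCombination] = None) -> None:
        self.config = config or SearchConfig()
        self.nn = nn or NNConfig()
        self.combinations = combinations

    def get_params(self, deep: bool = True) -> dict:
        return {"config": self.config, "nn": self.nn,
                "combinations": self.combinations}

    def set_params(self, **params) -> "PanelSearchCV":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    def fit(self, matrix: ExpressionMatrix, y=None) -> "PanelSearchCV":
        self.results_ = search_panels(matrix, self.config, self.nn,
                                      self.combinations)
        self.selected_ = select_models(self.results_,
                                       self.config.selection_threshold)
        return self
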