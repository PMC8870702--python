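"""Ensemble majority-vote classification of unknown samples.

Each blinded validation sample is classified many times (10,000 iterations
by default). Per iteration a stratified 90% subset of the labeled
adenoma/carcinoma samples is drawn, a fresh network is trained on the
panel's markers, and the unknown is assigned its argmax class. The final
call is the class receiving strictly more than half of the votes; an exact
tie is INDETERMINATE. The fraction of carcinoma votes doubles as the
continuous score for ROC analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .config import NNConfig, VoteConfig
from .containers import ExpressionMatrix, GroupLabel, INDETERMINATE
from .neural import train_batched
from .search import PanelCombination
from .seeding import child_seed

__all__ = ["VoteResult", "classify_sample", "classify_cohort",
           "MajorityVoteClassifier"]


@dataclass
class VoteResult:
    """Vote tally over the ensemble iterations for one unknown sample.

    ``call_sequence`` keeps the per-iteration predicted classes (in
    iteration order) for exchangeability diagnostics.
    """

    sample_id: str
    votes: Dict[str, int]
    vote_fraction_acc: float
    final_call: str
    n_iterations: int
    call_sequence: np.ndarray = None

    def __post_init__(self) -> None:
        if sum(self.votes.values()) != self.n_iterations:
            raise ValueError("vote counts must sum to n_iterations")


def _final_call(votes: Dict[str, int], n: int, threshold: float) -> str:
    for cls, count in votes.items():
        if count / n > threshold:
            return cls
    return INDETERMINATE


def _learners_per_class(n_class: int) -> int:
    """Size of the stratified 90% learner draw; always leaves >= 1 out."""
    return min(n_class - 1, max(1, int(round(0.9 * n_class))))


def classify_sample(
    known: ExpressionMatrix,
    unknown: pd.Series,
    combo: PanelCombination,
    nn: NNConfig = None,
    vote: VoteConfig = None,
    sample_id: str = None,
) -> VoteResult:
    """Ensemble-vote one unknown feature vector against the labeled cohort.

    ``unknown`` is a Series of expression values indexed by marker name (its
    ``name`` attribute provides the sample id unless given explicitly).
    Deterministic given (known, unknown, combo, configs): the per-sample
    child seed is derived from the vote seed and the sample id.
    """
    nn = nn or NNConfig()
    vote = vote or VoteConfig()
    if sample_id is None:
        sample_id = str(unknown.name) if unknown.name is not None else "unknown"

    sub = known.restrict_groups(vote.train_groups)
    sub = sub.subset_samples(sorted(sub.sample_ids))
    X_all = sub.feature_array(combo.assays)
    y_all = sub.groups.to_numpy()
    classes = np.array(sorted(np.unique(y_all)))
    if classes.size < 2:
        raise ValueError("known cohort must contain at least two classes")

    missing = [a for a in combo.assays if a not in unknown.index]
    if missing:
        raise ValueError(f"sample {sample_id}: markers absent from input: {missing}")
    x = unknown.loc[list(combo.assays)].to_numpy(dtype=float)
    if np.isnan(x).any():
        bad = combo.assays[int(np.flatnonzero(np.isnan(x))[0])]
        raise ValueError(
            f"sample {sample_id}: masked expression for marker {bad}"
        )

    B = vote.n_iterations
    rng = np.random.default_rng(child_seed(vote.seed, "sample", sample_id))

    if vote.resample_mode == "subsample_90":
        blocks = []
        for g in classes:
            rows = np.flatnonzero(y_all == g)
            if rows.size < 2:
                raise ValueError(f"group {g} needs >= 2 known samples")
            l_g = _learners_per_class(rows.size)
            draws = np.argsort(rng.random((B, rows.size)), axis=1)[:, :l_g]
            blocks.append(rows[draws])
        learn_idx = np.concatenate(blocks, axis=1)       # (B, n_learn)
    else:  # full_refit: same learners every iteration, fresh init only
        learn_idx = np.broadcast_to(np.arange(y_all.size), (B, y_all.size)).copy()

    init_seeds = rng.integers(0, 2**31, size=B)
    Y_learn = (y_all[learn_idx][:, :, None] == classes[None, None, :]).astype(float)
    nets = train_batched(X_all[learn_idx], Y_learn, classes, nn, init_seeds)
    pred = nets.predict(np.broadcast_to(x, (B, 1, x.size)))[:, 0]

    votes = {str(c): int(np.sum(pred == c)) for c in classes}
    frac_acc = votes.get(GroupLabel.ACC, 0) / B
    return VoteResult(
        sample_id=sample_id,
        votes=votes,
        vote_fraction_acc=float(frac_acc),
        final_call=_final_call(votes, B, vote.majority_threshold),
        n_iterations=B,
        call_sequence=pred,
    )


def classify_cohort(
    known: ExpressionMatrix,
    unknowns: ExpressionMatrix,
    combo: PanelCombination,
    nn: NNConfig = None,
    vote: VoteConfig = None,
) -> List[VoteResult]:
    """Classify every unknown sample independently.

    Per-sample child seeds make each result independent of the order the
    unknowns are presented in.
    """
    results = []
    for sample_id in unknowns.sample_ids:
        row = unknowns.values.loc[sample_id]
        row.name = sample_id
        results.append(classify_sample(known, row, combo, nn, vote,
                                       sample_id=sample_id))
    return results


class MajorityVoteClassifier:
    """sklearn-style wrapper: fit on the labeled cohort, predict unknowns.

    ``fit`` stores the labeled expression matrix; ``predict`` returns final
    majority calls for an unknown matrix and ``predict_vote_fraction`` the
    continuous carcinoma-vote fractions used for ROC analysis.
    """

    def __init__(self, combo: PanelCombination, nn: NNConfig = None,
                 vote: VoteConfig = None) -> None:
        self.combo = combo
        self.nn = nn or NNConfig()
        self.vote = vote or VoteConfig()

    def get_params(self, deep: bool = True) -> dict:
        return {"combo": self.combo, "nn": self.nn, "vote": self.vote}

    def set_params(self, **params) -> "MajorityVoteClassifier":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    def fit(self, known: ExpressionMatrix, y=None) -> "MajorityVoteClassifier":
        self.known_ = known
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "known_"):
            raise ValueError("classifier is not fitted")

    def vote_results(self, unknowns: ExpressionMatrix) -> List[VoteResult]:
        self._check_fitted()
        return classify_cohort(self.known_, unknowns, self.combo, self.nn,
                               self.vote)

    def predict(self, unknowns: ExpressionMatrix) -> np.ndarray:
        return np.array([r.final_call for r in self.vote_results(unknowns)])

    def predict_vote_fraction(self, unknowns: ExpressionMatrix) -> Dict[str, float]:
        return {r.sample_id: r.vote_fraction_acc
                for r in self.vote_results(unknowns)}
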