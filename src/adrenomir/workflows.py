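"""End-to-end study workflows on synthetic cohorts.

These functions wire the pipeline stages together under the study design:
generate a discovery (10 ACA / 10 ACC / 10 NAC) and a blinded validation
(22 ACA / 21 ACC) cohort, normalize, score candidate panels by repeated
learner-tester cross-validation, ensemble-vote the unknowns, and measure
diagnostic performance. They exist so that simulation studies (signal
recovery, null calibration, marker-ranking recovery) are reproducible
one-liners for tests, scripts and users alike.
"""

from __future__ import annotations

from typing import Dict, Mapping, Sequence, Tuple

import numpy as np

from .config import NNConfig, SearchConfig, VoteConfig
from .forest import ForestParams, rank_markers
from .metrics import confusion_from_calls, roc_from_scores
from .normalize import DeltaCtNormalizer
from .search import CANDIDATE_PANELS, cross_validate_combination
from .simulate import SyntheticSpec, default_spec, generate_cohort, spec_with_marker_effects
from .vote import classify_cohort

__all__ = [
    "TOP5_IMPORTANCE",
    "BEST_PANEL_MARKERS",
    "study_spec",
    "null_spec",
    "prepare_cohorts",
    "run_panel_recovery",
    "run_null_search",
    "run_null_validation",
    "run_importance_recovery",
]

#: Markers ranked most important for group classification in the discovery
#: analysis (random-forest mean decrease in accuracy).
TOP5_IMPORTANCE: Tuple[str, ...] = (
    "hsa-miR-503",
    "hsa-miR-483-3p",
    "hsa-miR-195",
    "hsa-miR-375",
    "hsa-miR-483-5p",
)

#: Markers carried by the three best-performing validation panels
#: (models 9, 16 and 17).
BEST_PANEL_MARKERS: Tuple[str, ...] = (
    "hsa-miR-195",
    "hsa-miR-210",
    "hsa-miR-375",
    "hsa-miR-483-5p",
    "hsa-miR-503",
)


def study_spec(markers: Sequence[str] = BEST_PANEL_MARKERS) -> SyntheticSpec:
    """Study-like conditions: 2.0 log2-unit effects on the named markers,
    0.5 log2-unit background effects on the remaining targets."""
    return spec_with_marker_effects(markers, strong_effect=2.0,
                                    background_effect=0.5)


def null_spec() -> SyntheticSpec:
    """No group differences anywhere (negative-control conditions)."""
    return default_spec(effect_log2=0.0, aca_vs_nac_log2=0.0)


def prepare_cohorts(spec: SyntheticSpec, seed: int):
    """Generate and normalize both cohorts.

    Returns (discovery_matrix, validation_matrix, truth) where the
    validation matrix is blinded (UNKNOWN labels) and ``truth`` holds its
    real ACA/ACC assignments.
    """
    normalizer = DeltaCtNormalizer()
    disc_table, _ = generate_cohort(spec, "discovery", seed=seed)
    val_table, truth = generate_cohort(spec, "validation", seed=seed)
    return (normalizer.fit_transform(disc_table),
            normalizer.fit_transform(val_table), truth)


def run_panel_recovery(
    seed: int,
    models: Sequence[int] = (9, 16, 17),
    n_reps: int = 200,
    n_iterations: int = 500,
    spec: SyntheticSpec = None,
) -> Dict[int, Dict[str, float]]:
    """Full pipeline on one synthetic study replicate.

    For each requested candidate panel: discovery cross-validation
    capability (adenoma-vs-carcinoma splits) and validation-set diagnostic
    metrics of the ensemble majority votes.
    """
    spec = spec or study_spec()
    discovery, validation, truth = prepare_cohorts(spec, seed)
    search_cfg = SearchConfig(n_reps=n_reps, group_mode="two_class", seed=seed)
    vote_cfg = VoteConfig(n_iterations=n_iterations, seed=seed)
    nn = NNConfig(seed=seed)

    out: Dict[int, Dict[str, float]] = {}
    for number in models:
        combo = CANDIDATE_PANELS[number]
        cv = cross_validate_combination(discovery, combo, search_cfg, nn)
        votes = classify_cohort(discovery, validation, combo, nn, vote_cfg)
        calls = {r.sample_id: r.final_call for r in votes}
        scores = {r.sample_id: r.vote_fraction_acc for r in votes}
        confusion = confusion_from_calls(calls, truth)
        roc = roc_from_scores(scores, truth)
        out[number] = {
            "capability": cv.capability,
            "selected": cv.capability >= search_cfg.selection_threshold,
            "sensitivity": confusion.sensitivity,
            "specificity": confusion.specificity,
            "auc": roc.auc,
            "npv": confusion.npv,
            "ppv": confusion.ppv,
            "indeterminate": confusion.n_indeterminate,
        }
    return out


def run_null_search(seed: int, n_reps: int = 200) -> Dict[str, float]:
    """Capability of all 24 candidate panels under the null (no effects)."""
    discovery, _, _ = prepare_cohorts(null_spec(), seed)
    cfg = SearchConfig(n_reps=n_reps, group_mode="two_class", seed=seed)
    nn = NNConfig(seed=seed)
    caps = {
        combo.label: cross_validate_combination(discovery, combo, cfg, nn).capability
        for combo in CANDIDATE_PANELS.values()
    }
    return caps


def run_null_validation(seed: int, model: int = 9,
                        n_iterations: int = 500) -> float:
    """Final-call accuracy on a null validation cohort (chance level)."""
    discovery, validation, truth = prepare_cohorts(null_spec(), seed)
    votes = classify_cohort(
        discovery, validation, CANDIDATE_PANELS[model],
        nn=NNConfig(seed=seed), vote=VoteConfig(n_iterations=n_iterations, seed=seed),
    )
    correct = [r.final_call == truth[r.sample_id] for r in votes]
    return float(np.mean(correct))


def run_importance_recovery(seed: int, n_trees: int = 500) -> Tuple[set, bool]:
    """Rank markers on a discovery cohort whose five largest effects sit on
    the literature top-5; report the recovered top-5 set and whether it
    matches."""
    spec = study_spec(markers=TOP5_IMPORTANCE)
    discovery, _, _ = prepare_cohorts(spec, seed)
    result = rank_markers(discovery,
                          params=ForestParams(n_trees=n_trees, seed=seed))
    top = set(result.top(5))
    return top, top == set(TOP5_IMPORTANCE)
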