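"""Re-running the validation stage on a transcribed per-sample data table.

The study's per-sample expression values live in its supplementary appendix,
which is not distributed with this package. If a user transcribes that
table, this module re-runs the ensemble validation of the three
best-performing panels (models 9, 16 and 17) on it and scores the calls.

Expected fixture layout (``directory``):

    discovery.csv   wide expression CSV (sample_id index, group column,
                    one column per marker, values = -dCt)
    validation.csv  same layout; group column holds the revealed ACA/ACC
                    labels, which are used only for scoring

Both files pass through :func:`adrenomir.io.read_expression_matrix`.
"""

from __future__ import annotations

import os
from typing import Dict, Mapping, Sequence, Tuple

import pandas as pd

from .config import NNConfig, VoteConfig
from .containers import ExpressionMatrix, GroupLabel
from .io import read_expression_matrix
from .metrics import evaluate_models
from .search import CANDIDATE_PANELS
from .vote import classify_cohort

__all__ = ["load_appendix_cohort", "reproduce_validation", "BEST_MODELS"]

#: Model numbers of the panels reported with sensitivity and specificity
#: both above 90%.
BEST_MODELS = (9, 16, 17)


def load_appendix_cohort(directory) -> Tuple[ExpressionMatrix, ExpressionMatrix]:
    """Load transcribed discovery and validation expression matrices.

    Raises FileNotFoundError when the transcription is absent — the package
    never substitutes synthetic data for the study's own measurements.
    """
    discovery_path = os.path.join(directory, "discovery.csv")
    validation_path = os.path.join(directory, "validation.csv")
    for path in (discovery_path, validation_path):
        if not os.path.exists(path):
            raise FileNotFoundError(
                f"transcribed appendix table not found at {path}; "
                "per-sample study data must be transcribed by the user"
            )
    return read_expression_matrix(discovery_path), read_expression_matrix(validation_path)


def reproduce_validation(
    directory,
    models: Sequence[int] = BEST_MODELS,
    n_iterations: int = 1000,
    seed: int = 0,
    nn: NNConfig = None,
) -> pd.DataFrame:
    """Ensemble-validate the chosen panels on the transcribed cohorts.

    Returns the diagnostic-performance table (sensitivity, specificity, AUC,
    NPV, PPV as percentages) for the requested model numbers.
    """
    discovery, validation = load_appendix_cohort(directory)
    truth = {s: validation.groups[s] for s in validation.sample_ids}
    unknowns = ExpressionMatrix(
        values=validation.values.copy(),
        groups=pd.Series(GroupLabel.UNKNOWN, index=validation.values.index),
        control_ref=validation.control_ref,
    )
    vote = VoteConfig(n_iterations=n_iterations, seed=seed)
    per_model: Dict[str, list] = {}
    for number in models:
        combo = CANDIDATE_PANELS[number]
        per_model[f"model {number}: {combo.label}"] = classify_cohort(
            discovery, unknowns, combo, nn=nn, vote=vote
        )
    return evaluate_models(per_model, truth)
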