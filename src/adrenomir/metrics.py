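"""Diagnostic performance: confusion metrics and ROC analysis.

Carcinoma (ACC) is the positive "patient" class and adenoma (ACA) the
negative "control" class, following the standard epidemiological convention.
Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), PPV = TP/(TP+FP),
NPV = TN/(TN+FN); an undefined denominator is reported as "not computed"
(None), never silently zero. INDETERMINATE calls are counted separately and
never enter the four confusion cells.

The ROC curve sweeps every distinct score threshold (call positive when
score >= t); the trapezoidal area equals the Mann-Whitney statistic
P(score_pos > score_neg) + 1/2 P(equal).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .containers import INDETERMINATE, GroupLabel

__all__ = [
    "ConfusionMetrics",
    "ROCCurve",
    "confusion_from_calls",
    "roc_from_scores",
    "evaluate_models",
]


def _ratio(num: int, den: int) -> Optional[float]:
    return None if den == 0 else num / den


@dataclass
class ConfusionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    positive_class: str = GroupLabel.ACC
    n_indeterminate: int = 0

    @property
    def sensitivity(self) -> Optional[float]:
        return _ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> Optional[float]:
        return _ratio(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> Optional[float]:
        return _ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> Optional[float]:
        return _ratio(self.tn, self.tn + self.fn)

    @property
    def n_scored(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def swapped(self) -> "ConfusionMetrics":
        """Metrics with the opposite positive class (role swap)."""
        return ConfusionMetrics(
            tp=self.tn, fp=self.fn, tn=self.tp, fn=self.fp,
            positive_class=(GroupLabel.ACA if self.positive_class == GroupLabel.ACC
                            else GroupLabel.ACC),
            n_indeterminate=self.n_indeterminate,
        )


@dataclass
class ROCCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("auc must lie in [0, 1]")


def confusion_from_calls(
    calls: Mapping[str, str],
    truth: Mapping[str, str],
    positive: str = GroupLabel.ACC,
) -> ConfusionMetrics:
    """Tabulate final calls against true ACA/ACC labels."""
    negative = GroupLabel.ACA if positive == GroupLabel.ACC else GroupLabel.ACC
    tp = fp = tn = fn = indet = 0
    for sample, call in calls.items():
        if sample not in truth:
            raise ValueError(f"no truth label for called sample {sample}")
        actual = truth[sample]
        if actual not in (GroupLabel.ACA, GroupLabel.ACC):
            raise ValueError(
                f"truth label for {sample} must be ACA or ACC, got {actual}"
            )
        if call == INDETERMINATE:
            indet += 1
            continue
        if call not in (GroupLabel.ACA, GroupLabel.ACC):
            raise ValueError(f"call for {sample} must be ACA, ACC or "
                             f"{INDETERMINATE}, got {call}")
        if call == positive:
            if actual == positive:
                tp += 1
            else:
                fp += 1
        else:
            if actual == negative:
                tn += 1
            else:
                fn += 1
    return ConfusionMetrics(tp=tp, fp=fp, tn=tn, fn=fn,
                            positive_class=positive, n_indeterminate=indet)


def roc_from_scores(
    scores: Mapping[str, float],
    truth: Mapping[str, str],
    positive: str = GroupLabel.ACC,
) -> ROCCurve:
    """ROC curve over all distinct score thresholds.

    ``scores`` maps sample id to a continuous score that is larger for the
    positive class (the carcinoma vote fraction); thresholding calls a
    sample positive when score >= t.
    """
    y = np.array([truth[s] == positive for s in scores], dtype=bool)
    s = np.array([scores[k] for k in scores], dtype=float)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires at least one sample of each class")

    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    # collapse tied scores: one operating point per distinct threshold
    distinct = np.flatnonzero(np.diff(s_sorted) != 0)
    cut = np.concatenate([distinct, [s_sorted.size - 1]])
    tp_cum = np.cumsum(y_sorted)[cut]
    fp_cum = np.cumsum(~y_sorted)[cut]
    tpr = np.concatenate([[0.0], tp_cum / n_pos])
    fpr = np.concatenate([[0.0], fp_cum / n_neg])
    thresholds = np.concatenate([[np.inf], s_sorted[cut]])
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


def _metrics_row(label: str, confusion: ConfusionMetrics,
                 roc: Optional[ROCCurve]) -> dict:
    def pct(x):
        return np.nan if x is None else 100.0 * x

    return {
        "model": label,
        "sensitivity_pct": pct(confusion.sensitivity),
        "specificity_pct": pct(confusion.specificity),
        "auc_pct": pct(roc.auc) if roc is not None else np.nan,
        "npv_pct": pct(confusion.npv),
        "ppv_pct": pct(confusion.ppv),
        "indeterminate": confusion.n_indeterminate,
    }


def plot_roc(curves: Mapping[str, "ROCCurve"], path) -> None:
    """Plot ROC curves (sensitivity vs 1 - specificity) to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for label, roc in curves.items():
        ax.plot(roc.fpr, roc.tpr, label=f"{label} (AUC {100 * roc.auc:.2f}%)")
    ax.plot([0, 1], [0, 1], linestyle=":", color="grey", linewidth=1)
    ax.set_xlabel("1 - Specificity")
    ax.set_ylabel("Sensitivity")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def evaluate_models(
    vote_results_per_model: Mapping[str, Sequence],
    truth: Mapping[str, str],
    positive: str = GroupLabel.ACC,
) -> pd.DataFrame:
    """Diagnostic-performance table, one row per panel.

    ``vote_results_per_model`` maps a panel label to its list of VoteResult
    objects. Percentages are rounded to two decimals, mirroring how such
    tables are reported.
    """
    if not vote_results_per_model:
        raise ValueError("evaluate_models requires at least one model")
    rows = []
    for label, results in vote_results_per_model.items():
        calls = {r.sample_id: r.final_call for r in results}
        scores = {r.sample_id: r.vote_fraction_acc for r in results}
        confusion = confusion_from_calls(calls, truth, positive=positive)
        roc = roc_from_scores(scores, truth, positive=positive)
        rows.append(_metrics_row(label, confusion, roc))
    df = pd.DataFrame.from_records(rows).set_index("model")
    pct_cols = [c for c in df.columns if c.endswith("_pct")]
    df[pct_cols] = df[pct_cols].round(2)
    return df
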