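"""Evaluation metrics for imbalanced per-residue classification.

Threshold metrics (sensitivity TPR, specificity TNR, precision, accuracy,
F1, Matthews correlation coefficient) are computed from the 2x2 confusion
table; a score exactly at the threshold is called positive.  Ranking metrics:
AUROC in its Mann-Whitney form (probability that a random positive outranks
a random negative, ties counted 1/2) and average precision as the exact step
summation ``AP = sum_n (R_n - R_{n-1}) P_n`` over the distinct-score
thresholds in descending order (no interpolation).

Any metric with a zero denominator is reported as 0 with a logged note, so
degenerate folds never crash an evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger("capsite")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class MetricsReport:
    """The full evaluation suite for one score vector."""

    TPR: float
    TNR: float
    Pre: float
    ACC: float
    F1: float
    MCC: float
    AUROC: float
    AP: float
    threshold: float
    n_residues: int

    def as_dict(self) -> dict[str, float]:
        return {
            "TPR": self.TPR, "TNR": self.TNR, "Pre": self.Pre,
            "ACC": self.ACC, "F1": self.F1, "MCC": self.MCC,
            "AUROC": self.AUROC, "AP": self.AP,
            "threshold": self.threshold, "n_residues": self.n_residues,
        }

    def __str__(self) -> str:
        lines = [f"residues evaluated: {self.n_residues}",
                 f"decision threshold: {self.threshold:g}"]
        for key in ("TPR", "TNR", "Pre", "ACC", "F1", "MCC", "AUROC", "AP"):
            lines.append(f"{key}: {getattr(self, key):.4f}")
        return "\n".join(lines)


def _check(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length vectors")
    return scores, labels


def confusion_counts(scores, labels, threshold: float = 0.5) -> ConfusionCounts:
    """Threshold scores (``>=`` is positive) and tabulate the 2x2 table."""
    scores, labels = _check(scores, labels)
    calls = scores >= threshold
    return ConfusionCounts(
        TP=int(np.sum(calls & (labels == 1))),
        FP=int(np.sum(calls & (labels == 0))),
        TN=int(np.sum(~calls & (labels == 0))),
        FN=int(np.sum(~calls & (labels == 1))),
    )


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.info("metric %s has zero denominator; reported as 0", name)
        return 0.0
    return num / den


def classification_metrics(c: ConfusionCounts) -> dict[str, float]:
    """TPR, TNR, Pre, ACC, F1 and MCC from a confusion table."""
    if c.total == 0:
        raise ValueError("empty confusion table")
    tpr = _safe_div(c.TP, c.TP + c.FN, "TPR")
    tnr = _safe_div(c.TN, c.TN + c.FP, "TNR")
    pre = _safe_div(c.TP, c.TP + c.FP, "Pre")
    acc = (c.TP + c.TN) / c.total
    f1 = _safe_div(2.0 * tpr * pre, tpr + pre, "F1")
    mcc_den = np.sqrt(
        float(c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    )
    mcc = _safe_div(float(c.TP) * c.TN - float(c.FN) * c.FP, mcc_den, "MCC")
    return {"TPR": tpr, "TNR": tnr, "Pre": pre, "ACC": acc, "F1": f1, "MCC": mcc}


def auroc_score(scores, labels) -> float:
    """Mann-Whitney AUROC: P(score_pos > score_neg) + 0.5 P(tie)."""
    scores, labels = _check(scores, labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("AUROC needs both classes")
    # rank-based formulation: O(n log n)
    order = np.argsort(scores, kind="mergesort")
    ranks = np.empty(scores.size)
    sorted_scores = scores[order]
    # midranks for ties
    i = 0
    while i < scores.size:
        j = i
        while j + 1 < scores.size and sorted_scores[j + 1] == sorted_scores[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    rank_sum = ranks[labels == 1].sum()
    u = rank_sum - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def average_precision(scores, labels) -> float:
    """Exact step-summed AP over descending distinct-score thresholds."""
    scores, labels = _check(scores, labels)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("average precision needs at least one positive")
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    y = labels[order]
    tp = np.cumsum(y)
    pred_pos = np.arange(1, scores.size + 1)
    # keep only the last row of each distinct-score block (the threshold)
    last = np.flatnonzero(np.r_[s[1:] != s[:-1], True])
    recall = tp[last] / n_pos
    precision = tp[last] / pred_pos[last]
    prev_recall = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - prev_recall) * precision))


def evaluate(
    scores, labels, threshold: float = 0.5, match_prevalence: bool = False
) -> MetricsReport:
    """Full report.  ``match_prevalence=True`` replaces the fixed threshold
    with the score quantile that calls as many positives as the labels have
    (a convention used by several interaction-site predictors)."""
    scores, labels = _check(scores, labels)
    if match_prevalence:
        n_pos = int(labels.sum())
        threshold = float(np.sort(scores)[::-1][max(n_pos - 1, 0)])
    counts = confusion_counts(scores, labels, threshold)
    out = classification_metrics(counts)
    return MetricsReport(
        **out,
        AUROC=auroc_score(scores, labels),
        AP=average_precision(scores, labels),
        threshold=threshold,
        n_residues=counts.total,
    )


def pr_curve(scores, labels) -> np.ndarray:
    """(threshold, recall, precision) rows for the optional TSV export."""
    scores, labels = _check(scores, labels)
    n_pos = int(labels.sum())
    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], labels[order]
    tp = np.cumsum(y)
    pred_pos = np.arange(1, scores.size + 1)
    last = np.flatnonzero(np.r_[s[1:] != s[:-1], True])
    return np.column_stack([s[last], tp[last] / n_pos, tp[last] / pred_pos[last]])
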