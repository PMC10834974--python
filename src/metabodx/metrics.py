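"""Closed-form classification metrics from confusion matrices and scores.

Undefined metrics (zero denominators on degenerate matrices or folds) are
reported as NaN, never coerced to 0.  Display rounding is half-up to two
decimals, the convention of clinical ML reports; raw values are kept
internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts of true/false positives/negatives: (tp, fp, fn, tn)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion matrix must contain at least one subject")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def sensitivity(cm: ConfusionMatrix) -> float:
    """TP / (TP + FN); NaN when no actual positives."""
    d = cm.tp + cm.fn
    return cm.tp / d if d else float("nan")


def specificity(cm: ConfusionMatrix) -> float:
    """TN / (TN + FP); NaN when no actual negatives."""
    d = cm.tn + cm.fp
    return cm.tn / d if d else float("nan")


def accuracy(cm: ConfusionMatrix) -> float:
    """(TP + TN) / total."""
    return (cm.tp + cm.tn) / cm.total


def precision(cm: ConfusionMatrix) -> float:
    """TP / (TP + FP); NaN when nothing was predicted positive."""
    d = cm.tp + cm.fp
    return cm.tp / d if d else float("nan")


def recall(cm: ConfusionMatrix) -> float:
    """Alias of sensitivity."""
    return sensitivity(cm)


def f1(cm: ConfusionMatrix) -> float:
    """Harmonic mean of precision and recall; NaN if either is undefined or both 0."""
    p, r = precision(cm), recall(cm)
    if np.isnan(p) or np.isnan(r) or (p + r) == 0:
        return float("nan")
    return 2 * p * r / (p + r)


def youden_index(cm: ConfusionMatrix) -> float:
    """sensitivity + specificity - 1."""
    return sensitivity(cm) + specificity(cm) - 1.0


def metric_report(cm: ConfusionMatrix) -> dict[str, float]:
    return {
        "sensitivity": sensitivity(cm),
        "specificity": specificity(cm),
        "accuracy": accuracy(cm),
        "precision": precision(cm),
        "recall": recall(cm),
        "f1": f1(cm),
        "youden_j": youden_index(cm),
    }


def auc_from_scores(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based ROC AUC of ``scores`` for the positive class in ``labels``.

    Midrank tie handling; orientation is fixed by the labels, so values below
    0.5 indicate anti-correlated scores.  ``labels`` must be boolean/0-1 with
    both classes present.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(s)
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def round_display(x: float, ndigits: int = 2) -> float:
    """Half-up rounding for report display (0.925 -> 0.93)."""
    if np.isnan(x):
        return float("nan")
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


__all__ = [
    "ConfusionMatrix",
    "sensitivity",
    "specificity",
    "accuracy",
    "precision",
    "recall",
    "f1",
    "youden_index",
    "metric_report",
    "auc_from_scores",
    "round_display",
]
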