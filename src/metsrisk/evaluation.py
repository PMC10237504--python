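"""Dichotomous and ranking metrics, including zone-level PPV arithmetic.

recall = TP/(TP+FN), specificity = TN/(TN+FP), balanced accuracy their
mean; AUC is the rank-based area under the ROC curve.  ``adjusted_ppv``
implements the reclassification arithmetic used when false positives
judged at-risk by an external index are counted as true positives:
(TP + reclassified) / (TP + FP).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = [
    "ConfusionCounts",
    "UndefinedMetricError",
    "confusion",
    "recall",
    "specificity",
    "balanced_accuracy",
    "auc",
    "ppv_npv",
    "adjusted_ppv",
    "round3",
]


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator is zero for the given counts."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(y_true, y_pred) -> ConfusionCounts:
    t = np.asarray(y_true).astype(bool)
    p = np.asarray(y_pred).astype(bool)
    if t.shape != p.shape:
        raise ValueError("y_true and y_pred differ in length")
    return ConfusionCounts(
        tp=int(np.sum(t & p)),
        fp=int(np.sum(~t & p)),
        tn=int(np.sum(~t & ~p)),
        fn=int(np.sum(t & ~p)),
    )


def recall(counts: ConfusionCounts) -> float:
    if counts.tp + counts.fn == 0:
        raise UndefinedMetricError("recall undefined: no actual positives")
    return counts.tp / (counts.tp + counts.fn)


def specificity(counts: ConfusionCounts) -> float:
    if counts.tn + counts.fp == 0:
        raise UndefinedMetricError("specificity undefined: no actual negatives")
    return counts.tn / (counts.tn + counts.fp)


def balanced_accuracy(recall_value: float, specificity_value: float) -> float:
    if not (0.0 <= recall_value <= 1.0 and 0.0 <= specificity_value <= 1.0):
        raise ValueError("recall and specificity must lie in [0, 1]")
    return (recall_value + specificity_value) / 2.0


def auc(scores, y) -> float:
    """Area under the ROC curve (rank-based, midranks for ties)."""
    y = np.asarray(y).astype(int)
    if y.min() == y.max():
        raise UndefinedMetricError("AUC undefined with a single class")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def ppv_npv(counts: ConfusionCounts) -> tuple[float, float]:
    if counts.tp + counts.fp == 0:
        raise UndefinedMetricError("PPV undefined: no predicted positives")
    if counts.tn + counts.fn == 0:
        raise UndefinedMetricError("NPV undefined: no predicted negatives")
    return (
        counts.tp / (counts.tp + counts.fp),
        counts.tn / (counts.tn + counts.fn),
    )


def adjusted_ppv(counts: ConfusionCounts, reclassified: int) -> float:
    """PPV after moving ``reclassified`` false positives into the numerator."""
    if reclassified < 0 or reclassified > counts.fp:
        raise ValueError("reclassified count must lie in [0, FP]")
    if counts.tp + counts.fp == 0:
        raise UndefinedMetricError("adjusted PPV undefined: no predicted positives")
    return (counts.tp + reclassified) / (counts.tp + counts.fp)


def round3(x: float) -> float:
    """Half-up rounding to three decimals (report display convention)."""
    return float(np.floor(x * 1000.0 + 0.5) / 1000.0)
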