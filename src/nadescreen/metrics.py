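"""Confusion-matrix metrics: MCC, F1, accuracy.

Positive class is "stable" (label 1) throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

logger = logging.getLogger(__name__)

__all__ = ["ConfusionMatrix", "confusion_matrix", "mcc", "f1_accuracy", "macro_f1"]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_matrix(truth: Sequence[int], predicted: Sequence[int]) -> ConfusionMatrix:
    if len(truth) != len(predicted):
        raise ValueError(
            f"label vectors differ in length: {len(truth)} vs {len(predicted)}")
    tp = fp = tn = fn = 0
    for t, p in zip(truth, predicted):
        if t not in (0, 1) or p not in (0, 1):
            raise ValueError(f"labels must be binary, got truth={t!r} pred={p!r}")
        if t == 1 and p == 1:
            tp += 1
        elif t == 0 and p == 1:
            fp += 1
        elif t == 0 and p == 0:
            tn += 1
        else:
            fn += 1
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient in [-1, 1].

    ``(TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))``; returns 0 by
    convention when any denominator factor vanishes.
    """
    if cm.total < 1:
        raise ValueError("confusion matrix is empty")
    denom = ((cm.tp + cm.fp) * (cm.tp + cm.fn)
             * (cm.tn + cm.fp) * (cm.tn + cm.fn))
    if denom == 0:
        logger.debug("degenerate confusion matrix %s: MCC set to 0", cm)
        return 0.0
    return (cm.tp * cm.tn - cm.fp * cm.fn) / math.sqrt(denom)


def f1_accuracy(cm: ConfusionMatrix) -> tuple[float, float]:
    """Stable-class F1 (0 on a degenerate denominator) and overall accuracy."""
    if cm.total < 1:
        raise ValueError("confusion matrix is empty")
    f1_denom = 2 * cm.tp + cm.fp + cm.fn
    f1 = 2 * cm.tp / f1_denom if f1_denom else 0.0
    accuracy = (cm.tp + cm.tn) / cm.total
    return f1, accuracy


def macro_f1(cm: ConfusionMatrix) -> float:
    """Unweighted mean of the stable-class and unstable-class F1 scores."""
    pos, _ = f1_accuracy(cm)
    neg_denom = 2 * cm.tn + cm.fn + cm.fp
    neg = 2 * cm.tn / neg_denom if neg_denom else 0.0
    return (pos + neg) / 2.0
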