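"""Classification evaluation indices over confusion counts.

Accuracy, precision, recall (sensitivity) and F1 on the 0-100 percentage
scale, as used when scoring lesion detectors.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ConfusionCounts",
    "UndefinedMetricError",
    "accuracy",
    "precision",
    "recall",
    "f1_score",
]


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator is zero; the message names the metric."""


@dataclass(frozen=True)
class ConfusionCounts:
    """True/false positive/negative counts of a binary decision."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool) or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / (TP + TN + FP + FN) x 100."""
    total = c.tp + c.tn + c.fp + c.fn
    if total == 0:
        raise UndefinedMetricError("accuracy undefined: all counts are zero")
    return 100.0 * (c.tp + c.tn) / total


def precision(c: ConfusionCounts) -> float:
    """TP / (TP + FP) x 100."""
    if c.tp + c.fp == 0:
        raise UndefinedMetricError("precision undefined: no positive predictions")
    return 100.0 * c.tp / (c.tp + c.fp)


def recall(c: ConfusionCounts) -> float:
    """TP / (TP + FN) x 100 (sensitivity)."""
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("recall undefined: no actual positives")
    return 100.0 * c.tp / (c.tp + c.fn)


def f1_score(c: ConfusionCounts) -> float:
    """Harmonic mean of precision and recall, x 100."""
    p = precision(c) / 100.0
    r = recall(c) / 100.0
    if p + r == 0:
        raise UndefinedMetricError("f1 undefined: precision + recall is zero")
    return 100.0 * 2.0 * p * r / (p + r)
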