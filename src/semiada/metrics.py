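"""Micro-averaged metrics from the class-averaged one-vs-rest confusion matrix.

Each class's binary confusion counts (TP, FP, TN, FN) are averaged over
classes; accuracy and micro-precision/recall/F1 are computed from those
averaged counts.  For single-label predictions the one-vs-rest totals
satisfy sum(FP) = sum(FN) = number of errors, so micro-P and micro-R
coincide; this degeneracy is a property of the construction and is
asserted, not hidden, by the tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

__all__ = ["ConfusionSummary", "MicroMetrics", "confusion_summary", "micro_metrics", "metrics_row"]


@dataclass(frozen=True)
class ConfusionSummary:
    labels: tuple[str, ...]
    tp: dict[str, int]
    fp: dict[str, int]
    tn: dict[str, int]
    fn: dict[str, int]
    n_examples: int

    @property
    def tp_bar(self) -> float:
        return sum(self.tp.values()) / len(self.labels)

    @property
    def fp_bar(self) -> float:
        return sum(self.fp.values()) / len(self.labels)

    @property
    def tn_bar(self) -> float:
        return sum(self.tn.values()) / len(self.labels)

    @property
    def fn_bar(self) -> float:
        return sum(self.fn.values()) / len(self.labels)


@dataclass(frozen=True)
class MicroMetrics:
    accuracy: float
    micro_p: float
    micro_r: float
    micro_f1: float

    def as_percent_row(self) -> tuple[float, float, float, float]:
        """Values scaled to percent at one decimal place, table style."""
        return tuple(round(100 * v, 1) for v in (self.accuracy, self.micro_p, self.micro_r, self.micro_f1))


def confusion_summary(
    truth: Sequence[str], predicted: Sequence[str], labels: Sequence[str]
) -> ConfusionSummary:
    """Exact per-class one-vs-rest counts for single-label predictions."""
    if len(truth) != len(predicted):
        raise ValueError("truth and predicted must have equal length")
    labels = tuple(labels)
    label_set = set(labels)
    for v in truth:
        if v not in label_set:
            raise ValueError(f"truth label {v!r} not in label set")
    for v in predicted:
        if v not in label_set:
            raise ValueError(f"predicted label {v!r} not in label set")
    tp = {lb: 0 for lb in labels}
    fp = {lb: 0 for lb in labels}
    tn = {lb: 0 for lb in labels}
    fn = {lb: 0 for lb in labels}
    for t, p in zip(truth, predicted):
        for lb in labels:
            if t == lb and p == lb:
                tp[lb] += 1
            elif t != lb and p == lb:
                fp[lb] += 1
            elif t == lb and p != lb:
                fn[lb] += 1
            else:
                tn[lb] += 1
    return ConfusionSummary(labels, tp, fp, tn, fn, len(truth))


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0.0:
        warnings.warn(f"{name} denominator is zero; defining the metric as 0", stacklevel=3)
        return 0.0
    return num / den


def micro_metrics(summary: ConfusionSummary) -> MicroMetrics:
    """Accuracy and micro-P/R/F1 evaluated on the class-averaged counts."""
    tp, fp, tn, fn = summary.tp_bar, summary.fp_bar, summary.tn_bar, summary.fn_bar
    acc = _safe_div(tp + tn, tp + fp + tn + fn, "accuracy")
    p = _safe_div(tp, tp + fp, "micro-precision")
    r = _safe_div(tp, tp + fn, "micro-recall")
    f1 = _safe_div(2 * p * r, p + r, "micro-F1")
    return MicroMetrics(acc, p, r, f1)


def metrics_row(mode: str, m: MicroMetrics) -> str:
    """One TSV row: mode then the four metrics in percent, 1 decimal place."""
    acc, p, r, f1 = m.as_percent_row()
    return f"{mode}\t{acc:.1f}\t{p:.1f}\t{r:.1f}\t{f1:.1f}"
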