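"""Confusion-matrix metrics: ACC, SN, SP, MCC, F1.

Positives are antioxidant proteins (label 1). Any metric whose denominator
is zero (e.g. sensitivity on a fold with no positives) is reported as 0 and
flagged in ``warnings`` so that cross-validation averaging stays defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import InputError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise InputError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    acc: float
    sn: float
    sp: float
    mcc: float
    f1: float
    counts: ConfusionCounts | None = None
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {"acc": self.acc, "sn": self.sn, "sp": self.sp,
             "mcc": self.mcc, "f1": self.f1}
        if self.counts is not None:
            d["counts"] = {"tp": self.counts.tp, "fp": self.counts.fp,
                           "tn": self.counts.tn, "fn": self.counts.fn}
        if self.warnings:
            d["warnings"] = list(self.warnings)
        return d


def confusion_from_predictions(y_true, y_pred) -> ConfusionCounts:
    """Tally a binary confusion matrix (1 = antioxidant positive)."""
    tp = fp = tn = fn = 0
    for t, p in zip(y_true, y_pred, strict=True):
        if t not in (0, 1) or p not in (0, 1):
            raise InputError("labels and predictions must be binary 0/1")
        if t == 1 and p == 1:
            tp += 1
        elif t == 0 and p == 1:
            fp += 1
        elif t == 0 and p == 0:
            tn += 1
        else:
            fn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _safe_div(num: float, den: float, name: str, warnings: list[str]) -> float:
    if den == 0:
        warnings.append(f"degenerate denominator in {name}; reported 0")
        return 0.0
    return num / den


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """ACC, SN, SP, MCC and F1 from confusion counts.

    MCC = (TN*TP - FN*FP) / sqrt((TN+FP)(FN+TP)(TN+FN)(TP+FP)).
    """
    if counts.total == 0:
        raise InputError("cannot compute metrics on zero samples")
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    warnings: list[str] = []
    acc = (tn + tp) / counts.total
    sn = _safe_div(tp, tp + fn, "SN", warnings)
    sp = _safe_div(tn, tn + fp, "SP", warnings)
    f1 = _safe_div(2 * tp, 2 * tp + fp + fn, "F1", warnings)
    denom = math.sqrt(
        float(tn + fp) * float(fn + tp) * float(tn + fn) * float(tp + fp)
    )
    mcc = _safe_div(float(tn) * tp - float(fn) * fp, denom, "MCC", warnings)
    return MetricsReport(acc=acc, sn=sn, sp=sp, mcc=mcc, f1=f1,
                         counts=counts, warnings=warnings)
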