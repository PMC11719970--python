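"""Confusion-matrix metrics, ROC construction and TPR-FPR threshold selection.

Metrics with a zero denominator are reported as 0.0 and flagged in
``MetricReport.degenerate`` rather than raising, so reports stay total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.total == 0:
            raise ValueError("confusion counts sum to zero")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricReport:
    """Scalar classification metrics; ``mcc`` is None for multi-class reports."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    mcc: float | None = None
    degenerate: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }
        if self.mcc is not None:
            d["mcc"] = self.mcc
        if self.degenerate:
            d["degenerate"] = list(self.degenerate)
        return d


@dataclass(frozen=True)
class ThresholdResult:
    threshold: float
    tpr: float
    fpr: float
    j: float


def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionCounts:
    """Exact binary confusion counts; class 1 is the positive (disease) class."""
    t = np.asarray(y_true)
    p = np.asarray(y_pred)
    if t.shape != p.shape or t.ndim != 1 or t.size == 0:
        raise ValueError("y_true and y_pred must be equal-length non-empty 1-D sequences")
    for arr, name in ((t, "y_true"), (p, "y_pred")):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} contains non-binary values")
    return ConfusionCounts(
        tp=int(np.sum((t == 1) & (p == 1))),
        fp=int(np.sum((t == 0) & (p == 1))),
        fn=int(np.sum((t == 1) & (p == 0))),
        tn=int(np.sum((t == 0) & (p == 0))),
    )


def _safe_div(num: float, den: float, name: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def binary_metrics(c: ConfusionCounts) -> MetricReport:
    """Accuracy, precision, recall, F1 and MCC from binary confusion counts."""
    flags: list[str] = []
    tp, fp, fn, tn = c.tp, c.fp, c.fn, c.tn
    accuracy = (tp + tn) / c.total
    precision = _safe_div(tp, tp + fp, "precision", flags)
    recall = _safe_div(tp, tp + fn, "recall", flags)
    f1 = _safe_div(2 * precision * recall, precision + recall, "f1", flags)
    mcc_den = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if mcc_den == 0:
        flags.append("mcc")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / mcc_den
    return MetricReport(accuracy, precision, recall, f1, mcc, tuple(flags))


def multiclass_metrics(
    y_true: Sequence, y_pred: Sequence, classes: Sequence
) -> MetricReport:
    """Accuracy plus macro-averaged one-vs-rest precision/recall/F1.

    Per-class terms with zero denominators count as 0 toward the macro mean
    and are flagged.
    """
    t = list(y_true)
    p = list(y_pred)
    if len(t) != len(p) or not t:
        raise ValueError("y_true and y_pred must be equal-length and non-empty")
    known = set(classes)
    unknown = (set(t) | set(p)) - known
    if unknown:
        raise ValueError(f"unknown labels: {sorted(map(str, unknown))}")
    n = len(t)
    accuracy = sum(a == b for a, b in zip(t, p)) / n
    flags: list[str] = []
    precisions, recalls, f1s = [], [], []
    for cls in classes:
        tp = sum(a == cls and b == cls for a, b in zip(t, p))
        fp = sum(a != cls and b == cls for a, b in zip(t, p))
        fn = sum(a == cls and b != cls for a, b in zip(t, p))
        prec = _safe_div(tp, tp + fp, f"precision[{cls}]", flags)
        rec = _safe_div(tp, tp + fn, f"recall[{cls}]", flags)
        f1 = _safe_div(2 * prec * rec, prec + rec, f"f1[{cls}]", flags)
        precisions.append(prec)
        recalls.append(rec)
        f1s.append(f1)
    k = len(list(classes))
    return MetricReport(
        accuracy=accuracy,
        precision=sum(precisions) / k,
        recall=sum(recalls) / k,
        f1=sum(f1s) / k,
        mcc=None,
        degenerate=tuple(flags),
    )


def roc_and_threshold(scores: Sequence[float], y_true: Sequence[int]) -> ThresholdResult:
    """Pick the threshold maximizing TPR - FPR under the rule score > t -> 1.

    Candidate thresholds are midpoints between consecutive distinct sorted
    scores plus sentinels below the minimum and above the maximum (clipped
    to [0, 1]).  Ties in TPR - FPR break toward the largest threshold, i.e.
    the fewest positive calls.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(y_true)
    if s.shape != t.shape or s.ndim != 1 or s.size == 0:
        raise ValueError("scores and y_true must be equal-length non-empty 1-D sequences")
    if not np.isin(t, (0, 1)).all():
        raise ValueError("y_true must be binary")
    n_pos = int(t.sum())
    n_neg = int(t.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to build a ROC curve")
    u = np.unique(s)
    candidates = [float(np.clip(u[0] - 0.5, 0.0, 1.0))]
    candidates.extend(((u[:-1] + u[1:]) / 2.0).tolist())
    candidates.append(float(np.clip(u[-1] + 0.5, 0.0, 1.0)))
    best: ThresholdResult | None = None
    for thr in candidates:
        pred = s > thr
        tpr = float(np.sum(pred & (t == 1))) / n_pos
        fpr = float(np.sum(pred & (t == 0))) / n_neg
        j = tpr - fpr
        # >= keeps the largest threshold among ties (candidates are increasing)
        if best is None or j >= best.j:
            best = ThresholdResult(float(thr), tpr, fpr, j)
    assert best is not None
    return best
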