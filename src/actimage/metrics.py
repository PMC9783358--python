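"""Confusion matrices and macro-averaged multiclass evaluation metrics.

Five scores are computed from a K x K confusion matrix (rows = true
class, columns = predicted class): overall accuracy (percent,
trace/total), and sensitivity, specificity, F1 and Matthews correlation
coefficient, each computed per class one-vs-rest from its TP/TN/FP/FN
counts and then macro-averaged (unweighted mean over classes):

    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    F1          = 2 TP / (2 TP + FP + FN)
    MCC         = (TP*TN - FP*FN) / sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN))

A class whose denominator is zero contributes 0 for that metric.
Macro averaging weights every activity equally, which is what makes the
scores informative on the imbalanced cohorts this pipeline targets.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .imu_io import ClassSet

__all__ = [
    "BinaryCounts",
    "ConfusionMatrix",
    "MetricReport",
    "binarize",
    "confusion",
    "report",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K prediction counts in the class set's fixed order."""

    counts: np.ndarray
    classes: ClassSet

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.classes)
        if counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {counts.shape}")
        if (counts < 0).any():
            raise ValueError("confusion counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, path: str | Path) -> None:
        frame = pd.DataFrame(
            self.counts, index=list(self.classes), columns=list(self.classes)
        )
        frame.to_csv(Path(path), index_label="true\\pred")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ConfusionMatrix":
        frame = pd.read_csv(Path(path), index_col=0)
        if list(frame.index) != list(frame.columns):
            raise ValueError(f"{path}: row and column class names differ")
        return cls(
            counts=frame.to_numpy(dtype=np.int64),
            classes=ClassSet(tuple(frame.columns)),
        )


@dataclass(frozen=True)
class BinaryCounts:
    """One-vs-rest counts for a single class."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(
    true: Sequence[str], pred: Sequence[str], classes: ClassSet
) -> ConfusionMatrix:
    """Count predictions: entry (i, j) is how often class i was
    predicted as class j.  Unknown labels are rejected by name."""
    if len(true) != len(pred):
        raise ValueError(f"label lists differ in length: {len(true)} vs {len(pred)}")
    for lab in list(true) + list(pred):
        if lab not in classes:
            raise ValueError(f"unknown label {lab!r}; classes are {tuple(classes)}")
    if len(true) == 0:
        counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    else:
        counts = _sk_confusion(list(true), list(pred), labels=list(classes))
    return ConfusionMatrix(counts=counts, classes=classes)


def binarize(cm: ConfusionMatrix, class_index: int) -> BinaryCounts:
    """One-vs-rest reduction for the class at ``class_index``."""
    c = cm.counts
    tp = int(c[class_index, class_index])
    fn = int(c[class_index].sum()) - tp
    fp = int(c[:, class_index].sum()) - tp
    tn = cm.total - tp - fn - fp
    return BinaryCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _safe_div(num: float, den: float) -> float:
    return num / den if den != 0 else 0.0


def _class_metrics(bc: BinaryCounts) -> dict[str, float]:
    tp, tn, fp, fn = bc.tp, bc.tn, bc.fp, bc.fn
    mcc_den = math.sqrt(
        float(tp + fn) * float(tn + fp) * float(tp + fp) * float(tn + fn)
    )
    return {
        "sensitivity": _safe_div(tp, tp + fn),
        "specificity": _safe_div(tn, tn + fp),
        "f1": _safe_div(2 * tp, 2 * tp + fp + fn),
        "mcc": _safe_div(tp * tn - fp * fn, mcc_den),
    }


@dataclass
class MetricReport:
    """Overall accuracy plus the four macro-averaged per-class scores."""

    accuracy: float  # percent, [0, 100]
    sensitivity: float
    specificity: float
    f1: float
    mcc: float
    per_class_counts: dict[str, BinaryCounts] = field(default_factory=dict)
    per_class_metrics: dict[str, dict[str, float]] = field(default_factory=dict)

    def rounded(self) -> dict[str, float]:
        """Display convention: accuracy to 1 decimal, others to 3
        (round half up)."""
        def rhu(x: float, d: int) -> float:
            scale = 10**d
            return math.floor(x * scale + 0.5) / scale

        return {
            "accuracy": rhu(self.accuracy, 1),
            "sensitivity": rhu(self.sensitivity, 3),
            "specificity": rhu(self.specificity, 3),
            "f1": rhu(self.f1, 3),
            "mcc": rhu(self.mcc, 3),
        }

    def to_json(self, path: str | Path) -> None:
        payload = {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "f1": self.f1,
            "mcc": self.mcc,
            "rounded": self.rounded(),
            "per_class": {
                name: {
                    "tp": bc.tp,
                    "tn": bc.tn,
                    "fp": bc.fp,
                    "fn": bc.fn,
                    **self.per_class_metrics[name],
                }
                for name, bc in self.per_class_counts.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def report(cm: ConfusionMatrix) -> MetricReport:
    """Compute the five evaluation scores from a confusion matrix."""
    if cm.total == 0:
        raise ValueError("cannot compute metrics from an all-zero confusion matrix")
    per_counts: dict[str, BinaryCounts] = {}
    per_metrics: dict[str, dict[str, float]] = {}
    for i, name in enumerate(cm.classes):
        bc = binarize(cm, i)
        per_counts[name] = bc
        per_metrics[name] = _class_metrics(bc)
    macro = {
        key: float(np.mean([m[key] for m in per_metrics.values()]))
        for key in ("sensitivity", "specificity", "f1", "mcc")
    }
    return MetricReport(
        accuracy=100.0 * float(np.trace(cm.counts)) / cm.total,
        per_class_counts=per_counts,
        per_class_metrics=per_metrics,
        **macro,
    )
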