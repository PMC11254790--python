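"""Identification metrics: confusion matrix, accuracy, macro averages.

Overall accuracy is the fraction of correctly identified beats
(trace / total).  Precision, sensitivity (recall) and F1 are computed
one-vs-rest per subject from TP/FP/TN/FN counts and macro-averaged —
every subject weighs equally regardless of how many beats it contributed.
Any 0/0 ratio is defined as 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts[i, j] = beats of true class i predicted as class j."""

    counts: np.ndarray
    label_order: list[str]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        n = len(self.label_order)
        if c.shape != (n, n):
            raise ValueError(f"counts must be {n}x{n}, got {c.shape}")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class ClassMetrics:
    label: str
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float  # per-class binary accuracy (TP+TN)/total
    precision: float
    sensitivity: float
    f1: float


@dataclass(frozen=True)
class EvalReport:
    confusion: ConfusionMatrix
    accuracy: float
    macro_precision: float
    macro_sensitivity: float
    macro_f1: float
    per_class: list[ClassMetrics]

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_sensitivity": self.macro_sensitivity,
            "macro_f1": self.macro_f1,
            "label_order": self.confusion.label_order,
            "confusion": self.confusion.counts.tolist(),
            "per_class": [
                {
                    "label": m.label, "tp": m.tp, "fp": m.fp, "tn": m.tn,
                    "fn": m.fn, "accuracy": m.accuracy,
                    "precision": m.precision, "sensitivity": m.sensitivity,
                    "f1": m.f1,
                }
                for m in self.per_class
            ],
        }


def _ratio(num: float, den: float) -> float:
    if den == 0:
        logger.warning("0/0 metric encountered; defined as 0")
        return 0.0
    return num / den


def confusion_matrix(
    y_true: np.ndarray, y_pred: np.ndarray, label_order: list[str]
) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    index = {lab: i for i, lab in enumerate(label_order)}
    counts = np.zeros((len(label_order), len(label_order)), dtype=int)
    for t, p in zip(y_true, y_pred):
        if t not in index or p not in index:
            raise ValueError(f"label outside label_order: true={t!r} pred={p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, list(label_order))


def per_class_metrics(cm: ConfusionMatrix) -> list[ClassMetrics]:
    """One-vs-rest TP/FP/TN/FN and the derived ratios for every class."""
    c = cm.counts
    total = cm.total
    out = []
    for i, lab in enumerate(cm.label_order):
        tp = int(c[i, i])
        fn = int(c[i, :].sum() - tp)
        fp = int(c[:, i].sum() - tp)
        tn = total - tp - fp - fn
        precision = _ratio(tp, tp + fp)
        sensitivity = _ratio(tp, tp + fn)
        f1 = _ratio(2 * precision * sensitivity, precision + sensitivity)
        out.append(
            ClassMetrics(
                label=lab, tp=tp, fp=fp, tn=tn, fn=fn,
                accuracy=_ratio(tp + tn, total),
                precision=precision, sensitivity=sensitivity, f1=f1,
            )
        )
    return out


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of correctly identified beats: trace / total."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix has no accuracy")
    return float(np.trace(cm.counts)) / cm.total


def evaluate(
    y_true: np.ndarray, y_pred: np.ndarray, label_order: list[str]
) -> EvalReport:
    """Confusion matrix, overall accuracy, and macro-averaged metrics."""
    cm = confusion_matrix(y_true, y_pred, label_order)
    per_class = per_class_metrics(cm)
    return EvalReport(
        confusion=cm,
        accuracy=overall_accuracy(cm),
        macro_precision=float(np.mean([m.precision for m in per_class])),
        macro_sensitivity=float(np.mean([m.sensitivity for m in per_class])),
        macro_f1=float(np.mean([m.f1 for m in per_class])),
        per_class=per_class,
    )
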