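"""Confusion-matrix accuracy metrics for crop classification maps.

The three standard remote-sensing scores:

* OA (overall accuracy)  = trace / total — fraction of correct test pixels;
* AA (average accuracy)  = unweighted mean of per-class recalls, robust to
  the heavy class imbalance of agricultural scenes;
* Kappa = (p_o - p_e) / (1 - p_e), chance-corrected agreement with expected
  agreement p_e computed from the matrix marginals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["ConfusionMatrix", "confusion_matrix", "overall_accuracy",
           "average_accuracy", "kappa", "per_class_accuracy"]


@dataclass
class ConfusionMatrix:
    """k x k counts; rows = true class, columns = predicted class."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray,
                     n_classes: int) -> ConfusionMatrix:
    """Tally 1-based true/predicted labels into a k x k matrix."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("label arrays must have equal length")
    if ((y_true < 1) | (y_true > n_classes)).any() \
            or ((y_pred < 1) | (y_pred > n_classes)).any():
        raise ValueError("labels must be in 1..n_classes")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (y_true - 1, y_pred - 1), 1)
    return ConfusionMatrix(counts)


def _as_counts(cm) -> np.ndarray:
    return cm.counts if isinstance(cm, ConfusionMatrix) else np.asarray(cm)


def overall_accuracy(cm) -> float:
    counts = _as_counts(cm)
    total = counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(counts) / total)


def per_class_accuracy(cm) -> np.ndarray:
    """Per-class recall; NaN for classes with no test samples."""
    counts = _as_counts(cm)
    row = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(row > 0, np.diag(counts) / row, np.nan)


def average_accuracy(cm) -> float:
    acc = per_class_accuracy(cm)
    if np.isnan(acc).any():
        warnings.warn("classes without test samples excluded from AA",
                      stacklevel=2)
    if np.isnan(acc).all():
        raise ValueError("no class has test samples")
    return float(np.nanmean(acc))


def kappa(cm) -> float:
    counts = _as_counts(cm).astype(np.float64)
    total = counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(counts) / total
    p_e = float((counts.sum(axis=1) * counts.sum(axis=0)).sum()) / total ** 2
    if p_e >= 1.0:
        if p_o == 1.0:
            return 1.0   # all mass on one diagonal cell: perfect agreement
        raise ValueError("expected agreement is 1; kappa undefined")
    return float((p_o - p_e) / (1.0 - p_e))
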