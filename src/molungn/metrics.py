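"""Multiclass evaluation metrics.

Accuracy, weighted recall, per-class F1, macro F1 and weighted F1, computed
from the C x C confusion matrix.  For single-label multiclass predictions
the weighted recall equals the accuracy algebraically:

    Recall_weighted = sum_i (support_i / total) * (TP_i / support_i)
                    = sum_i TP_i / total = trace / total = Accuracy.

Both are still reported separately because the formulas are part of the
reporting contract.  Classes with Precision + Recall = 0 contribute an F1 of
0; macro F1 averages over all C classes, so classes absent from the truth
pull the macro score down (documented convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MetricsReport", "compute_metrics", "confusion_matrix"]


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray,
                     C: int) -> np.ndarray:
    cm = np.zeros((C, C), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


@dataclass
class MetricsReport:
    accuracy: float
    recall_weighted: float
    f1_macro: float
    f1_weighted: float
    precision_per_class: np.ndarray
    recall_per_class: np.ndarray
    f1_per_class: np.ndarray
    support: np.ndarray
    confusion: np.ndarray

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "recall_weighted": self.recall_weighted,
            "f1_macro": self.f1_macro,
            "f1_weighted": self.f1_weighted,
            "precision_per_class": self.precision_per_class.tolist(),
            "recall_per_class": self.recall_per_class.tolist(),
            "f1_per_class": self.f1_per_class.tolist(),
            "support": self.support.tolist(),
            "confusion": self.confusion.tolist(),
        }

    def summary(self) -> str:
        lines = [
            f"accuracy         {self.accuracy:.4f}",
            f"recall_weighted  {self.recall_weighted:.4f}",
            f"f1_weighted      {self.f1_weighted:.4f}",
            f"f1_macro         {self.f1_macro:.4f}",
            "class  precision  recall  f1      support",
        ]
        for i in range(len(self.support)):
            lines.append(f"{i:<6d} {self.precision_per_class[i]:<10.4f}"
                         f"{self.recall_per_class[i]:<8.4f}"
                         f"{self.f1_per_class[i]:<8.4f}"
                         f"{int(self.support[i])}")
        return "\n".join(lines)


def compute_metrics(y_true, y_pred, C: int) -> MetricsReport:
    """Confusion-matrix metrics for single-label multiclass predictions."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.size == 0:
        raise ValueError("cannot compute metrics on an empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    if y_true.min() < 0 or y_true.max() >= C or \
            y_pred.min() < 0 or y_pred.max() >= C:
        raise ValueError("class codes out of range [0, C)")
    cm = confusion_matrix(y_true, y_pred, C)
    total = cm.sum()
    tp = np.diag(cm).astype(float)
    support = cm.sum(axis=1).astype(float)
    predicted = cm.sum(axis=0).astype(float)

    with np.errstate(invalid="ignore", divide="ignore"):
        recall = np.where(support > 0, tp / np.where(support > 0, support, 1), 0.0)
        precision = np.where(predicted > 0, tp / np.where(predicted > 0, predicted, 1), 0.0)
        pr = precision + recall
        f1 = np.where(pr > 0, 2 * precision * recall / np.where(pr > 0, pr, 1), 0.0)

    weights = support / total
    accuracy = float(tp.sum() / total)
    recall_weighted = float((weights * recall).sum())
    f1_macro = float(f1.mean())  # all C classes, absent ones contribute 0
    f1_weighted = float((weights * f1).sum())
    return MetricsReport(accuracy, recall_weighted, f1_macro, f1_weighted,
                         precision, recall, f1, support.astype(np.int64), cm)
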