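"""Multiclass evaluation: confusion matrix, accuracy, macro recall/F1."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class Metrics:
    confusion: np.ndarray  # rows = true class, cols = predicted
    accuracy: float
    macro_f1: float
    macro_recall: float
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            "macro_recall": self.macro_recall,
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "f1": self.f1.tolist(),
        }


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int) -> np.ndarray:
    """Count matrix for labels 1..n_classes (rows = true, cols = predicted)."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    for name, y in (("true", y_true), ("predicted", y_pred)):
        bad = y[(y < 1) | (y > n_classes)]
        if bad.size:
            raise ValueError(f"unseen {name} label value(s): {np.unique(bad).tolist()}")
    C = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(C, (y_true - 1, y_pred - 1), 1)
    return C


def metrics_from_confusion(C: np.ndarray) -> Metrics:
    C = np.asarray(C, dtype=int)
    n = C.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(C).astype(float)
    support = C.sum(axis=1).astype(float)
    predicted = C.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        recall = np.where(support > 0, tp / support, 0.0)
        precision = np.where(predicted > 0, tp / predicted, 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    return Metrics(
        confusion=C,
        accuracy=float(tp.sum() / n),
        macro_f1=float(f1.mean()),
        macro_recall=float(recall.mean()),
        precision=precision,
        recall=recall,
        f1=f1,
    )
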