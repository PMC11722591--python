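"""Classification metrics from one-vs-rest contingency counts.

Accuracy, precision, recall and F1 are computed per class from the TP / FP /
FN / TN contingency and macro-averaged (unweighted mean over classes).  A
class with a zero denominator — never predicted, or absent from the labels —
contributes 0 to the average; the harmonic-mean F1 is likewise 0 when
precision + recall is 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EvalCounts", "compute_counts", "macro_metrics", "confusion_matrix"]


@dataclass
class EvalCounts:
    """Per-class one-vs-rest contingency: each array has length n_classes,
    and TP + FP + FN + TN = N for every class."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray

    @property
    def n_classes(self) -> int:
        return len(self.tp)

    @property
    def n(self) -> int:
        return int(self.tp[0] + self.fp[0] + self.fn[0] + self.tn[0])


def _validate(predictions, labels, n_classes):
    predictions = np.asarray(predictions, dtype=np.int64)
    labels = np.asarray(labels, dtype=np.int64)
    if predictions.shape != labels.shape or predictions.ndim != 1:
        raise ValueError("predictions and labels must be equal-length 1-D arrays")
    if predictions.size == 0:
        raise ValueError("empty prediction vector")
    for arr, name in ((predictions, "prediction"), (labels, "label")):
        if arr.min() < 0 or arr.max() >= n_classes:
            raise ValueError(f"{name} out of range [0, {n_classes})")
    return predictions, labels


def compute_counts(predictions, labels, n_classes: int) -> EvalCounts:
    """One-vs-rest TP/FP/FN/TN per class."""
    predictions, labels = _validate(predictions, labels, n_classes)
    tp = np.zeros(n_classes, dtype=np.int64)
    fp = np.zeros(n_classes, dtype=np.int64)
    fn = np.zeros(n_classes, dtype=np.int64)
    tn = np.zeros(n_classes, dtype=np.int64)
    for c in range(n_classes):
        pred_c = predictions == c
        true_c = labels == c
        tp[c] = np.sum(pred_c & true_c)
        fp[c] = np.sum(pred_c & ~true_c)
        fn[c] = np.sum(~pred_c & true_c)
        tn[c] = np.sum(~pred_c & ~true_c)
    return EvalCounts(tp, fp, fn, tn)


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.zeros_like(num, dtype=np.float64)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    return out


def macro_metrics(counts: EvalCounts) -> dict[str, float]:
    """Accuracy plus macro-averaged precision, recall and F1 (fractions in [0, 1])."""
    n = counts.n
    if n == 0:
        raise ValueError("no samples")
    precision = _safe_div(counts.tp, counts.tp + counts.fp)
    recall = _safe_div(counts.tp, counts.tp + counts.fn)
    f1 = _safe_div(2 * precision * recall, precision + recall)
    # every correct prediction is the TP of exactly one class
    accuracy = float(counts.tp.sum()) / n
    return {
        "accuracy": accuracy,
        "precision": float(precision.mean()),
        "recall": float(recall.mean()),
        "f1": float(f1.mean()),
    }


def confusion_matrix(predictions, labels, n_classes: int, normalize: bool = False):
    """Rows = true class, columns = predicted class.  With ``normalize``,
    rows are scaled to percentages (rows with zero support stay zero)."""
    predictions, labels = _validate(predictions, labels, n_classes)
    mat = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(mat, (labels, predictions), 1)
    if normalize:
        sums = mat.sum(axis=1, keepdims=True)
        out = np.zeros(mat.shape, dtype=np.float64)
        nz = sums[:, 0] > 0
        out[nz] = mat[nz] / sums[nz] * 100.0
        return out
    return mat
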