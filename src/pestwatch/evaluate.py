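"""Identification metrics: confusion matrices, per-class precision/recall/F1
and overall accuracy.

Per-class precision P_i = TP/(TP+FP), recall R_i = TP/(TP+FN) and the
harmonic mean F1_i = 2 P_i R_i / (P_i + R_i); accuracy is the fraction of
correct predictions. Classes with zero support (or never predicted) get an
explicit ``None`` with a flag rather than a silent 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["confusion", "metrics", "EvalReport"]


def confusion(y_true, y_pred, n_classes: int) -> np.ndarray:
    """Confusion matrix with entry (i, j) = count of true class i predicted j."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be equal-length 1-D arrays")
    if len(y_true) == 0:
        raise ValueError("empty label arrays")
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        if arr.min() < 0 or arr.max() >= n_classes:
            raise ValueError(f"{name} contains labels outside [0, {n_classes})")
    m = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(m, (y_true, y_pred), 1)
    return m


@dataclass
class EvalReport:
    """Per-class and overall identification metrics.

    ``precision``/``recall``/``f1`` hold ``None`` for classes where the metric
    is undefined (no predictions / no support); ``undefined`` lists them.
    """

    matrix: np.ndarray
    precision: list[float | None]
    recall: list[float | None]
    f1: list[float | None]
    accuracy: float
    undefined: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "confusion_matrix": self.matrix.tolist(),
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "accuracy": self.accuracy,
            "undefined_classes": self.undefined,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def metrics(matrix: np.ndarray) -> EvalReport:
    """Compute precision/recall/F1 per class and overall accuracy from a
    confusion matrix of counts."""
    m = np.asarray(matrix, dtype=np.int64)
    if m.ndim != 2 or m.shape[0] != m.shape[1] or m.size == 0:
        raise ValueError("need a nonempty square count matrix")
    if (m < 0).any():
        raise ValueError("counts must be nonnegative")
    total = m.sum()
    if total == 0:
        raise ValueError("matrix holds no observations")

    tp = np.diag(m).astype(float)
    support = m.sum(axis=1).astype(float)     # TP + FN
    predicted = m.sum(axis=0).astype(float)   # TP + FP

    precision: list[float | None] = []
    recall: list[float | None] = []
    f1: list[float | None] = []
    undefined: list[int] = []
    for i in range(m.shape[0]):
        p = tp[i] / predicted[i] if predicted[i] > 0 else None
        r = tp[i] / support[i] if support[i] > 0 else None
        if p is None or r is None:
            undefined.append(i)
            f = None
        elif p + r == 0:
            f = 0.0
        else:
            f = 2 * p * r / (p + r)
        precision.append(p)
        recall.append(r)
        f1.append(f)

    return EvalReport(matrix=m, precision=precision, recall=recall, f1=f1,
                      accuracy=float(tp.sum() / total), undefined=undefined)
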