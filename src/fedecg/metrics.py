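"""Multiclass diagnostic metrics over the 4 rhythm classes.

All quantities derive from the 4x4 confusion matrix (rows = true class,
columns = predicted class).  Per class, one-vs-rest:

    precision   P  = TP / (TP + FP)
    sensitivity S  = TP / (TP + FN)        (recall)
    specificity Sp = TN / (TN + FP)
    F1             = 2 P S / (P + S)

plus overall accuracy, Cohen's kappa

    kappa = (p_o - p_e) / (1 - p_e),  p_o = trace/n,
    p_e = sum_k row_k * col_k / n^2,

and the multiclass Matthews correlation coefficient in its covariance
(Gorodkin) form.  Every 0/0 case returns 0 with a logged warning rather than
raising.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .labels import CLASSES, label_index

__all__ = [
    "MetricsReport",
    "confusion_matrix",
    "per_class_metrics",
    "kappa",
    "mcc",
    "evaluate_model",
]

logger = logging.getLogger(__name__)


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.warning("%s has zero denominator; returning 0 by convention", what)
        return 0.0
    return num / den


def confusion_matrix(y_true, y_pred, classes=CLASSES) -> np.ndarray:
    """Count matrix with entry (i, j) = true class i predicted as class j."""
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    k = len(classes)
    cm = np.zeros((k, k), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[label_index(t) if isinstance(t, str) else int(t),
           label_index(p) if isinstance(p, str) else int(p)] += 1
    return cm


def per_class_metrics(cm: np.ndarray) -> tuple[dict[str, dict[str, float]], float]:
    """One-vs-rest P/S/Sp/F1 per class, plus overall accuracy."""
    cm = np.asarray(cm)
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    out = {}
    for i, cls in enumerate(CLASSES):
        tp = cm[i, i]
        fp = cm[:, i].sum() - tp
        fn = cm[i, :].sum() - tp
        tn = total - tp - fp - fn
        p = _safe_div(tp, tp + fp, f"precision[{cls}]")
        s = _safe_div(tp, tp + fn, f"sensitivity[{cls}]")
        sp = _safe_div(tn, tn + fp, f"specificity[{cls}]")
        f1 = _safe_div(2 * p * s, p + s, f"F1[{cls}]")
        out[cls] = {"precision": p, "sensitivity": s, "specificity": sp, "f1": f1}
    accuracy = cm.trace() / total
    return out, float(accuracy)


def kappa(cm: np.ndarray) -> float:
    """Cohen's kappa: chance-corrected agreement."""
    cm = np.asarray(cm, dtype=float)
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    p_o = cm.trace() / total
    p_e = float((cm.sum(axis=1) * cm.sum(axis=0)).sum()) / total**2
    return float(np.clip(_safe_div(p_o - p_e, 1.0 - p_e, "kappa"), -1.0, 1.0))


def mcc(cm: np.ndarray) -> float:
    """Multiclass Matthews correlation coefficient (covariance form)."""
    cm = np.asarray(cm, dtype=float)
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    t_k = cm.sum(axis=1)  # true (row) totals
    p_k = cm.sum(axis=0)  # predicted (column) totals
    c = cm.trace()
    num = c * total - float(t_k @ p_k)
    den = np.sqrt(total**2 - float(p_k @ p_k)) * np.sqrt(total**2 - float(t_k @ t_k))
    return float(np.clip(_safe_div(num, den, "mcc"), -1.0, 1.0))


@dataclass
class MetricsReport:
    """Confusion matrix with per-class and aggregate statistics."""

    confusion: np.ndarray
    per_class: dict[str, dict[str, float]]
    accuracy: float
    kappa: float
    mcc: float

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "MetricsReport":
        cm = confusion_matrix(y_true, y_pred)
        per_cls, acc = per_class_metrics(cm)
        return cls(confusion=cm, per_class=per_cls, accuracy=acc, kappa=kappa(cm), mcc=mcc(cm))

    def to_frame(self) -> pd.DataFrame:
        """Per-class table in the P / S / Sp / F1 layout."""
        rows = [
            {
                "class": cls,
                "P": m["precision"],
                "S": m["sensitivity"],
                "Sp": m["specificity"],
                "F1": m["f1"],
            }
            for cls, m in self.per_class.items()
        ]
        return pd.DataFrame(rows).set_index("class")

    def summary(self) -> str:
        table = self.to_frame().round(4).to_string()
        return (
            f"{table}\n"
            f"accuracy = {self.accuracy:.4f}  kappa = {self.kappa:.4f}  "
            f"mcc = {self.mcc:.4f}  n = {int(self.confusion.sum())}"
        )

    def __str__(self) -> str:
        return self.summary()


def evaluate_model(predict_proba_fn, records) -> MetricsReport:
    """Score a model on records; ties at argmax go to the lowest class index."""
    if not records:
        raise ValueError("empty test set")
    y_true = [r.label for r in records]
    y_pred = [CLASSES[int(np.argmax(predict_proba_fn(r)))] for r in records]
    return MetricsReport.from_predictions(y_true, y_pred)
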