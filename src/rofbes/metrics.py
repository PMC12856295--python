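"""Binary-classification evaluation: confusion counts, ratio metrics, ROC/AUC.

The positive class is label 1 throughout.  Ratio metrics with an empty
denominator are reported as 0.0 together with an ``undefined`` flag, so that
fold tables stay rectangular instead of dropping cells.  AUC uses the
trapezoidal rule over the ROC curve, which is identical to the Mann–Whitney
U statistic with half credit for score ties.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve

__all__ = [
    "ConfusionMatrix",
    "MetricsRecord",
    "confusion",
    "classification_metrics",
    "f1_score",
    "roc_auc",
    "aggregate_folds",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def as_array(self) -> np.ndarray:
        """2x2 array with rows = true class (0, 1), columns = predicted."""
        return np.array([[self.tn, self.fp], [self.fn, self.tp]])


@dataclass
class MetricsRecord:
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float | None = None
    undefined: set[str] = field(default_factory=set)
    train_time: float = 0.0
    test_time: float = 0.0
    cm: ConfusionMatrix | None = None

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc": self.auc,
            "train_time": self.train_time,
            "test_time": self.test_time,
        }


def _check_binary(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must contain only labels 0 and 1")
    return arr.astype(int)


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """Count TP/TN/FP/FN with class 1 positive."""
    y_true = _check_binary(y_true, "y_true")
    y_pred = _check_binary(y_pred, "y_pred")
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn)


def classification_metrics(cm: ConfusionMatrix) -> MetricsRecord:
    """Accuracy, precision, recall and F1 from confusion counts.

    Zero-denominator ratios are reported as 0.0 and named in the record's
    ``undefined`` set.
    """
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    undefined: set[str] = set()
    accuracy = (cm.tp + cm.tn) / cm.total

    if cm.tp + cm.fp > 0:
        precision = cm.tp / (cm.tp + cm.fp)
    else:
        precision = 0.0
        undefined.add("precision")
    if cm.tp + cm.fn > 0:
        recall = cm.tp / (cm.tp + cm.fn)
    else:
        recall = 0.0
        undefined.add("recall")
    if precision + recall > 0:
        f1 = 2.0 * precision * recall / (precision + recall)
    else:
        f1 = 0.0
        undefined.add("f1")

    return MetricsRecord(
        accuracy=accuracy, precision=precision, recall=recall, f1=f1,
        undefined=undefined,
    )


def f1_score(y_true, y_pred) -> float:
    """Positive-class F1 (harmonic mean of precision and recall)."""
    return classification_metrics(confusion(y_true, y_pred)).f1


def roc_auc(y_true, scores) -> tuple[np.ndarray, float | None]:
    """ROC curve points and trapezoidal AUC.

    Returns (curve, auc) where curve is an array of (fpr, tpr) rows swept over
    the unique score thresholds.  Single-class truth makes AUC undefined and
    returns None for it.
    """
    y_true = _check_binary(y_true, "y_true")
    scores = np.asarray(scores, dtype=float)
    if len(y_true) != len(scores):
        raise ValueError("y_true and scores must have equal length")
    if len(np.unique(y_true)) < 2:
        return np.empty((0, 2)), None
    fpr, tpr, _ = roc_curve(y_true, scores)
    curve = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    return curve, auc


def aggregate_folds(records: list[MetricsRecord]) -> MetricsRecord:
    """Arithmetic mean of each metric across fold records.

    AUC is averaged over the records where it is defined; it is None if no
    record defines it.
    """
    if not records:
        raise ValueError("need at least one record")
    aucs = [r.auc for r in records if r.auc is not None]
    return MetricsRecord(
        accuracy=float(np.mean([r.accuracy for r in records])),
        precision=float(np.mean([r.precision for r in records])),
        recall=float(np.mean([r.recall for r in records])),
        f1=float(np.mean([r.f1 for r in records])),
        auc=float(np.mean(aucs)) if aucs else None,
        undefined=set().union(*(r.undefined for r in records)),
        train_time=float(np.mean([r.train_time for r in records])),
        test_time=float(np.mean([r.test_time for r in records])),
    )
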