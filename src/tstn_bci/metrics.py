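"""Confusion-matrix metrics for the 3-class decoding problem.

Accuracy is the confusion-matrix trace over the total; specificity and F1
are computed one-versus-rest per class and macro-averaged (the symmetric
default for a single summary number in a multiclass task).  Zero-denominator
conventions: precision/recall/F1 are 0 when undefined; specificity is 1 when
there are no negatives at all.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.metrics import confusion_matrix

from .io import CLASS_NAMES, DataError


@dataclasses.dataclass
class MetricsReport:
    confusion: np.ndarray            # rows = true class, cols = predicted
    accuracy: float
    specificity_macro: float
    f1_macro: float
    per_class: dict[str, dict[str, float]]
    n: int

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "specificity_macro": self.specificity_macro,
            "f1_macro": self.f1_macro,
            "per_class": self.per_class,
        }


def metrics_from_confusion(cm: np.ndarray) -> MetricsReport:
    """All metrics from a (true x predicted) count matrix."""
    cm = np.asarray(cm, dtype=np.int64)
    if cm.shape != (len(CLASS_NAMES), len(CLASS_NAMES)):
        raise DataError(f"confusion matrix must be {len(CLASS_NAMES)}x{len(CLASS_NAMES)}")
    if (cm < 0).any():
        raise DataError("confusion counts must be nonnegative")
    total = int(cm.sum())
    if total == 0:
        raise DataError("metrics undefined for empty input")
    accuracy = float(np.trace(cm) / total)
    per_class: dict[str, dict[str, float]] = {}
    specs, f1s = [], []
    for k, name in enumerate(CLASS_NAMES):
        tp = cm[k, k]
        fn = cm[k].sum() - tp
        fp = cm[:, k].sum() - tp
        tn = total - tp - fn - fp
        recall = tp / (tp + fn) if tp + fn else 0.0
        precision = tp / (tp + fp) if tp + fp else 0.0
        spec = tn / (tn + fp) if tn + fp else 1.0
        f1 = (
            2 * precision * recall / (precision + recall)
            if precision + recall
            else 0.0
        )
        specs.append(spec)
        f1s.append(f1)
        per_class[name] = {
            "accuracy": float(recall),
            "specificity": float(spec),
            "f1": float(f1),
        }
    return MetricsReport(
        confusion=cm,
        accuracy=accuracy,
        specificity_macro=float(np.mean(specs)),
        f1_macro=float(np.mean(f1s)),
        per_class=per_class,
        n=total,
    )


def compute_metrics(labels, predictions) -> MetricsReport:
    """Metrics from per-trial true labels and predictions."""
    labels = np.asarray(labels, dtype=np.int64)
    predictions = np.asarray(predictions, dtype=np.int64)
    if labels.shape != predictions.shape:
        raise DataError("labels and predictions must have equal length")
    if labels.size == 0:
        raise DataError("metrics undefined for empty input")
    codes = np.arange(len(CLASS_NAMES))
    if not (np.isin(labels, codes).all() and np.isin(predictions, codes).all()):
        raise DataError(f"labels must be integer codes 0..{len(CLASS_NAMES) - 1}")
    cm = confusion_matrix(labels, predictions, labels=codes)
    return metrics_from_confusion(cm)
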