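"""Confusion matrix, the metric panel, ROC/AUC and the error histogram.

Malignant is the positive class throughout. The panel follows the
standard definitions, reported as percentages:

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    specificity = TN / (TN + FP)
    sensitivity = TP / (TP + FN)
    precision   = TP / (TP + FP)

Two AUC-style quantities are computed. ``auc_ratio`` is the plain ratio
sensitivity/specificity (a legacy summary some reports print under the
AUC heading); ``roc_auc`` is the trapezoidal area under the
TPR-vs-FPR curve and is the headline value. A metric with a zero
denominator is reported as undefined (None), never silently as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = [
    "POSITIVE_LABEL", "ConfusionMatrix2x2", "MetricsReport",
    "confusion", "metrics", "auc_ratio", "roc_auc", "error_histogram",
]

POSITIVE_LABEL = "malignant"


@dataclass(frozen=True)
class ConfusionMatrix2x2:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricsReport:
    """Percent-scale panel; None marks an undefined (0/0) entry."""

    accuracy: float | None
    specificity: float | None
    sensitivity: float | None
    precision: float | None
    auc_ratio: float | None = None
    roc_auc: float | None = None

    def as_dict(self) -> dict:
        return {
            "accuracy_pct": self.accuracy,
            "specificity_pct": self.specificity,
            "sensitivity_pct": self.sensitivity,
            "precision_pct": self.precision,
            "auc_ratio": self.auc_ratio,
            "roc_auc_pct": self.roc_auc,
        }


def confusion(y_true: Sequence, y_pred: Sequence,
              positive=POSITIVE_LABEL) -> ConfusionMatrix2x2:
    """Tally TP/FP/FN/TN with ``positive`` as the positive class."""
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    labels = set(y_true) | set(y_pred)
    if len(labels) > 2:
        raise ValueError(f"labels are not binary: {sorted(map(str, labels))}")
    if positive not in labels and len(labels) == 2:
        raise ValueError(f"positive label {positive!r} not present in {sorted(map(str, labels))}")
    tp = fp = fn = tn = 0
    for t, p in zip(y_true, y_pred):
        if p == positive:
            if t == positive:
                tp += 1
            else:
                fp += 1
        else:
            if t == positive:
                fn += 1
            else:
                tn += 1
    return ConfusionMatrix2x2(tp=tp, fp=fp, fn=fn, tn=tn)


def _pct(num: int, den: int) -> float | None:
    return 100.0 * num / den if den > 0 else None


def metrics(cm: ConfusionMatrix2x2) -> MetricsReport:
    """Accuracy / specificity / sensitivity / precision as percentages."""
    report = MetricsReport(
        accuracy=_pct(cm.tp + cm.tn, cm.total),
        specificity=_pct(cm.tn, cm.tn + cm.fp),
        sensitivity=_pct(cm.tp, cm.tp + cm.fn),
        precision=_pct(cm.tp, cm.tp + cm.fp),
    )
    report.auc_ratio = auc_ratio(cm)
    return report


def auc_ratio(cm: ConfusionMatrix2x2) -> float | None:
    """Sensitivity / specificity; None when either is undefined or
    specificity is zero."""
    sens = _pct(cm.tp, cm.tp + cm.fn)
    spec = _pct(cm.tn, cm.tn + cm.fp)
    if sens is None or spec is None or spec == 0:
        return None
    return sens / spec


def roc_auc(y_true: Sequence, scores: Sequence[float],
            positive=POSITIVE_LABEL) -> float:
    """Trapezoidal area under the ROC curve, in percent."""
    y = np.asarray([1 if t == positive else 0 for t in y_true])
    if len(set(y)) < 2:
        raise ValueError("roc_auc requires both classes in y_true")
    return 100.0 * float(roc_auc_score(y, np.asarray(scores, dtype=np.float64)))


def error_histogram(targets: Sequence[float], outputs: Sequence[float],
                    n_bins: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of (target − output) over ``n_bins`` equal-width bins
    spanning the observed error range. Returns (bin_edges, counts)."""
    t = np.asarray(targets, dtype=np.float64)
    o = np.asarray(outputs, dtype=np.float64)
    if t.size == 0 or t.shape != o.shape:
        raise ValueError("targets and outputs must be non-empty and equal-length")
    errors = t - o
    counts, edges = np.histogram(errors, bins=n_bins)
    return edges, counts
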