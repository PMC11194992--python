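"""Binary-classifier evaluation: confusion matrix, score metrics, ROC/AUC.

The six scores reported for the Parkinson's / healthy-control task:
accuracy, sensitivity (recall on the positive class), specificity,
precision, F1 and the area under the ROC curve.  Cells with a zero
denominator yield 0 with a warning flag rather than raising, so batch
evaluation stays total.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["ConfusionMatrix", "MetricsReport", "confusion", "metrics", "roc_auc"]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    auc: float | None = None
    counts: ConfusionMatrix | None = None
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        d = {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "f1": self.f1,
            "auc": self.auc,
            "warnings": self.warnings,
        }
        if self.counts is not None:
            d["counts"] = {
                "tp": self.counts.tp,
                "tn": self.counts.tn,
                "fp": self.counts.fp,
                "fn": self.counts.fn,
            }
        return json.dumps(d, indent=2)

    def to_table(self) -> str:
        """Plain-text table of the six scores."""
        rows = [
            ("Accuracy", self.accuracy),
            ("Sensitivity", self.sensitivity),
            ("Specificity", self.specificity),
            ("Precision", self.precision),
            ("F1-Score", self.f1),
        ]
        if self.auc is not None:
            rows.append(("AUC-ROC", self.auc))
        width = max(len(r[0]) for r in rows)
        lines = [f"{name:<{width}}  {100 * value:7.2f}%" for name, value in rows]
        return "\n".join(lines)


def confusion(labels: Sequence, predictions: Sequence, positive_label="PD") -> ConfusionMatrix:
    """Tally the four confusion-matrix cells with an explicit positive label."""
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape or labels.ndim != 1 or labels.size == 0:
        raise ValueError("labels and predictions must be equal-length non-empty 1-D")
    values = set(np.unique(labels)) | set(np.unique(predictions))
    if len(values) > 2:
        raise ValueError(f"inputs are not binary: values {sorted(map(str, values))}")
    y = labels == positive_label
    yhat = predictions == positive_label
    return ConfusionMatrix(
        tp=int(np.sum(y & yhat)),
        tn=int(np.sum(~y & ~yhat)),
        fp=int(np.sum(~y & yhat)),
        fn=int(np.sum(y & ~yhat)),
    )


def _safe_div(num: float, den: float, name: str, warnings: list[str]) -> float:
    if den == 0:
        warnings.append(f"{name}: zero denominator, reported as 0")
        return 0.0
    return num / den


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, sensitivity, specificity, precision and F1 from counts."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    warns: list[str] = []
    accuracy = (cm.tp + cm.tn) / cm.total
    sensitivity = _safe_div(cm.tp, cm.tp + cm.fn, "sensitivity", warns)
    specificity = _safe_div(cm.tn, cm.tn + cm.fp, "specificity", warns)
    precision = _safe_div(cm.tp, cm.tp + cm.fp, "precision", warns)
    f1 = _safe_div(2 * precision * sensitivity, precision + sensitivity, "f1", warns)
    return MetricsReport(
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        precision=precision,
        f1=f1,
        counts=cm,
        warnings=warns,
    )


def roc_auc(scores: Sequence[float], labels: Sequence, positive_label="PD") -> float:
    """Area under the ROC curve by trapezoidal integration over thresholds.

    Equals the probability that a random positive outscores a random
    negative, with ties counted one half.  Requires both classes present.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels) == positive_label
    if scores.shape != y.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")

    # Sweep thresholds from high to low; each distinct score adds one ROC
    # vertex.  Tied scores move TPR and FPR jointly, which the trapezoid
    # integrates as the half-credit diagonal.
    order = np.argsort(-scores, kind="stable")
    y_sorted = y[order]
    s_sorted = scores[order]
    distinct = np.r_[np.nonzero(np.diff(s_sorted))[0], y.size - 1]
    tps = np.cumsum(y_sorted)[distinct]
    fps = (distinct + 1) - tps
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    return float(np.trapezoid(tpr, fpr))
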