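"""Evaluation metrics for labeled test cohorts.

MSI is the positive class throughout.  ``roc_auc`` is the rank-based
(Mann-Whitney) AUC with midrank tie handling; ``confusion_metrics`` computes
accuracy, F1, precision, sensitivity and specificity from hard status calls.
Zero-denominator ratios are reported as 0 with a warning so reports stay
machine-parseable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .errors import ValidationError


@dataclass
class MetricsReport:
    auc: float | None
    accuracy: float
    f1: float
    precision: float
    sensitivity: float
    specificity: float
    n_msi: int
    n_mss: int
    threshold: float | None = None

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "accuracy": self.accuracy,
            "f1": self.f1,
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "n_msi": self.n_msi,
            "n_mss": self.n_mss,
            "threshold": self.threshold,
        }


def _binary(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "US":
        bad = set(arr) - {"MSI", "MSS"}
        if bad:
            raise ValidationError(f"labels must be MSI or MSS, got {sorted(bad)}")
        return np.array([1 if v == "MSI" else 0 for v in arr], dtype=np.int64)
    return arr.astype(np.int64)


def roc_auc(scores: Sequence[float], labels) -> float:
    """Rank-based AUC: P(random MSI sample outscores a random MSS sample)."""
    s = np.asarray(scores, dtype=np.float64)
    y = _binary(labels)
    if s.size != y.size:
        raise ValidationError("scores and labels must align")
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC requires both classes present")
    ranks = rankdata(s)  # midranks handle ties
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reported as 0", stacklevel=3)
        return 0.0
    return num / den


def confusion_metrics(statuses, labels, threshold: float | None = None) -> MetricsReport:
    """Accuracy/F1/precision/sensitivity/specificity from MSI/MSS calls."""
    pred = _binary(statuses)
    truth = _binary(labels)
    if pred.size != truth.size:
        raise ValidationError("predictions and labels must align")
    if pred.size == 0:
        raise ValidationError("empty prediction list")
    tp = int(((pred == 1) & (truth == 1)).sum())
    fp = int(((pred == 1) & (truth == 0)).sum())
    tn = int(((pred == 0) & (truth == 0)).sum())
    fn = int(((pred == 0) & (truth == 1)).sum())
    sensitivity = _safe_ratio(tp, tp + fn, "sensitivity")
    specificity = _safe_ratio(tn, tn + fp, "specificity")
    precision = _safe_ratio(tp, tp + fp, "precision")
    accuracy = (tp + tn) / pred.size
    f1 = _safe_ratio(2 * precision * sensitivity, precision + sensitivity, "F1")
    return MetricsReport(
        auc=None,
        accuracy=accuracy,
        f1=f1,
        precision=precision,
        sensitivity=sensitivity,
        specificity=specificity,
        n_msi=int(truth.sum()),
        n_mss=int((1 - truth).sum()),
        threshold=threshold,
    )


def evaluate(scores, statuses, labels, threshold: float | None = None) -> MetricsReport:
    """Full report: rank AUC from scores plus confusion metrics from calls."""
    report = confusion_metrics(statuses, labels, threshold=threshold)
    report.auc = roc_auc(scores, labels)
    return report
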