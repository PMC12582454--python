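"""Confusion-matrix metrics, one-vs-rest ROC/AUC and the paired t-test.

Accuracy, macro precision/recall/F1 and Cohen's kappa are computed
definitionally from the confusion matrix (rows = truth, columns =
prediction); macro averaging is used throughout — with the balanced class
sizes of the target datasets macro and micro averages nearly coincide.
ROC/AUC and the t-test delegate to scikit-learn / SciPy.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

__all__ = [
    "confusion_matrix", "MetricsReport", "classification_metrics",
    "roc_auc", "TTestResult", "paired_t_test", "per_class_kappa",
]


def confusion_matrix(y_true, y_pred, n_classes: int) -> np.ndarray:
    """``counts[i, j]`` = number of samples with true class i predicted j."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    for name, y in (("y_true", y_true), ("y_pred", y_pred)):
        if y.size and (y.min() < 0 or y.max() >= n_classes):
            raise ValueError(f"{name} contains labels outside [0, {n_classes})")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


@dataclass
class MetricsReport:
    """Macro-averaged metrics plus the per-class breakdown (fractions in [0, 1])."""
    accuracy: float
    precision: float
    recall: float
    f1: float
    kappa: float
    auc: float = float("nan")
    per_class: Dict[str, List[float]] = field(default_factory=dict)
    averaging: str = "macro"

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f1": self.f1, "kappa": self.kappa,
            "auc": self.auc, "averaging": self.averaging,
            "per_class": self.per_class,
        }


def classification_metrics(cm: np.ndarray) -> MetricsReport:
    """Accuracy, macro precision/recall/F1 and Cohen's kappa from a matrix.

    Per-class metrics with an empty denominator (no predictions or no truth
    for that class) are defined as 0 and a warning is emitted.
    """
    cm = np.asarray(cm, dtype=np.float64)
    total = cm.sum()
    if total <= 0:
        raise ValueError("confusion matrix is empty")
    diag = np.diag(cm)
    col = cm.sum(axis=0)
    row = cm.sum(axis=1)
    if np.any(col == 0) or np.any(row == 0):
        warnings.warn("empty class row/column; its per-class metric is set to 0",
                      stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(col > 0, diag / np.maximum(col, 1e-300), 0.0)
        recall = np.where(row > 0, diag / np.maximum(row, 1e-300), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / np.maximum(denom, 1e-300), 0.0)
    accuracy = diag.sum() / total
    p_o = accuracy
    p_e = (row * col).sum() / total ** 2
    kappa = 0.0 if p_e == 1.0 else (p_o - p_e) / (1.0 - p_e)
    return MetricsReport(
        accuracy=float(accuracy),
        precision=float(precision.mean()),
        recall=float(recall.mean()),
        f1=float(f1.mean()),
        kappa=float(kappa),
        per_class={
            "precision": precision.tolist(),
            "recall": recall.tolist(),
            "f1": f1.tolist(),
        },
    )


def roc_auc(y_true, scores) -> dict:
    """One-vs-rest ROC/AUC per class plus micro (headline) and macro averages.

    ``scores`` rows are class-probability vectors.  Ties count 0.5 (the
    Mann-Whitney convention used by scikit-learn).
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=np.float64)
    classes = np.unique(y_true)
    if classes.size < 2:
        raise ValueError("ROC analysis needs at least two classes in y_true")
    if scores.ndim != 2:
        raise ValueError("scores must be (n_samples, n_classes)")
    n_classes = scores.shape[1]
    per_class = []
    for c in range(n_classes):
        pos = (y_true == c).astype(int)
        per_class.append(float(roc_auc_score(pos, scores[:, c]))
                         if 0 < pos.sum() < len(pos) else float("nan"))
    onehot = np.eye(n_classes)[y_true]
    micro = float(roc_auc_score(onehot.ravel(), scores.ravel()))
    macro = float(np.nanmean(per_class))
    return {"per_class": per_class, "micro": micro, "macro": macro, "auc": micro}


@dataclass
class TTestResult:
    mean_difference: float
    t_statistic: float
    p_value: float
    n_pairs: int


def paired_t_test(a: Sequence[float], b: Sequence[float]) -> TTestResult:
    """Two-sided paired t-test on matched per-class values (df = n - 1)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length 1-d samples with n >= 2")
    d = a - b
    if np.allclose(d.var(ddof=1), 0.0):
        raise ValueError("zero-variance differences: paired t-test undefined")
    t, p = stats.ttest_rel(a, b)
    return TTestResult(mean_difference=float(d.mean()), t_statistic=float(t),
                       p_value=float(p), n_pairs=int(a.size))


def per_class_kappa(y_true, y_pred, n_classes: int) -> np.ndarray:
    """One-vs-rest Cohen's kappa per class (class-wise agreement measure)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    out = np.empty(n_classes)
    for c in range(n_classes):
        cm = confusion_matrix((y_true == c).astype(int), (y_pred == c).astype(int), 2)
        out[c] = classification_metrics(cm).kappa
    return out
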