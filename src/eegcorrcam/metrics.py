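"""Confusion matrices and macro one-vs-rest fold metrics.

For a K-class task each fold is summarised by a K x K confusion matrix
(rows = true class, columns = predicted) and four percentages: accuracy
(trace / total) plus sensitivity, specificity and precision computed
one-vs-rest per class and macro-averaged without class weighting.  Folds
are aggregated as mean and sample (n-1) standard deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion


@dataclass
class FoldResult:
    """Confusion matrix and the four per-fold metrics (percent)."""

    confusion: np.ndarray
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    fold: int = -1
    test_indices: np.ndarray | None = None

    METRICS = ("accuracy", "sensitivity", "specificity", "precision")

    def as_dict(self) -> dict:
        return {
            "fold": self.fold,
            "confusion": self.confusion.tolist(),
            **{m: getattr(self, m) for m in self.METRICS},
        }


@dataclass
class CVSummary:
    """Per-fold results plus mean and SD of each metric."""

    folds: list[FoldResult]
    mean: dict[str, float]
    sd: dict[str, float]

    def as_dict(self) -> dict:
        return {
            "folds": [f.as_dict() for f in self.folds],
            "mean": self.mean,
            "sd": self.sd,
        }


def confusion(y_true, y_pred, n_classes: int) -> np.ndarray:
    """K x K integer confusion matrix; entry (t, p) counts true t predicted p."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size == 0:
        return np.zeros((n_classes, n_classes), dtype=int)
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        if arr.min() < 0 or arr.max() >= n_classes:
            raise ValueError(f"{name} contains indices outside [0, {n_classes})")
    return _sk_confusion(y_true, y_pred, labels=np.arange(n_classes))


def _macro(values: list[float | None], name: str) -> float:
    defined = [v for v in values if v is not None]
    if len(defined) < len(values):
        warnings.warn(
            f"{name}: {len(values) - len(defined)} class term(s) undefined "
            f"(zero denominator); excluded from the macro mean"
        )
    return float(np.mean(defined)) if defined else float("nan")


def summarize(cm: np.ndarray) -> FoldResult:
    """Accuracy plus macro one-vs-rest sensitivity/specificity/precision.

    Per class c: TP = cm[c, c], FN = row c minus TP, FP = column c minus
    TP, TN = the rest.  A class whose denominator is zero is excluded from
    that metric's macro mean with a warning.  All values are percentages.
    """
    cm = np.asarray(cm)
    total = cm.sum()
    if total <= 0:
        raise ValueError("confusion matrix is empty")
    k = cm.shape[0]
    accuracy = float(np.trace(cm)) / total * 100.0
    sens: list[float | None] = []
    spec: list[float | None] = []
    prec: list[float | None] = []
    for c in range(k):
        tp = cm[c, c]
        fn = cm[c, :].sum() - tp
        fp = cm[:, c].sum() - tp
        tn = total - tp - fn - fp
        sens.append(tp / (tp + fn) * 100.0 if tp + fn > 0 else None)
        spec.append(tn / (tn + fp) * 100.0 if tn + fp > 0 else None)
        prec.append(tp / (tp + fp) * 100.0 if tp + fp > 0 else None)
    return FoldResult(
        confusion=cm,
        accuracy=accuracy,
        sensitivity=_macro(sens, "sensitivity"),
        specificity=_macro(spec, "specificity"),
        precision=_macro(prec, "precision"),
    )


def normalized_confusion(cm: np.ndarray) -> np.ndarray:
    """Row-normalised confusion matrix (rows sum to 1; empty rows stay 0)."""
    cm = np.asarray(cm, dtype=float)
    sums = cm.sum(axis=1, keepdims=True)
    return np.divide(cm, sums, out=np.zeros_like(cm), where=sums > 0)


def aggregate_folds(results: list[FoldResult]) -> CVSummary:
    """Mean and sample (n-1) SD of each metric across folds.

    With a single fold the SD is reported as 0 with a warning.
    """
    if not results:
        raise ValueError("no fold results to aggregate")
    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    for m in FoldResult.METRICS:
        vals = np.array([getattr(r, m) for r in results], dtype=float)
        mean[m] = float(np.mean(vals))
        if len(vals) < 2:
            warnings.warn("single fold: standard deviation reported as 0")
            sd[m] = 0.0
        else:
            sd[m] = float(np.std(vals, ddof=1))
    return CVSummary(list(results), mean, sd)
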