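"""Classification metrics, ROC/AUC, prediction-entropy uncertainty,
IQR outlier masking, Wilcoxon pairwise comparison and permutation
importance."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve, auc as _trapezoid_auc

from .grid import Grid24_2

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion",
    "metrics_from_confusion",
    "roc_auc",
    "prediction_entropy",
    "iqr_outlier_mask",
    "compare_wilcoxon",
    "permutation_importance",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts with GL as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricsReport:
    """Accuracy/precision/sensitivity/F on [0,1]; undefined ratios are None."""

    accuracy: float
    precision: Optional[float]
    sensitivity: Optional[float]
    f_score: Optional[float]
    auc: Optional[float] = None
    entropy_mean: Optional[float] = None
    entropy_sd: Optional[float] = None

    def as_percent(self) -> Dict[str, Optional[float]]:
        out = {}
        for k in ("accuracy", "precision", "sensitivity", "f_score", "auc"):
            v = getattr(self, k)
            out[k] = None if v is None else 100.0 * v
        return out


def confusion(labels: Sequence[int], predictions: Sequence[int]) -> ConfusionMatrix:
    y = np.asarray(labels).astype(int)
    yhat = np.asarray(predictions).astype(int)
    if y.shape != yhat.shape:
        raise ValueError("labels and predictions must have equal length")
    if not (np.isin(y, (0, 1)).all() and np.isin(yhat, (0, 1)).all()):
        raise ValueError("labels and predictions must be binary 0/1")
    return ConfusionMatrix(
        tp=int(((y == 1) & (yhat == 1)).sum()),
        fp=int(((y == 0) & (yhat == 1)).sum()),
        fn=int(((y == 1) & (yhat == 0)).sum()),
        tn=int(((y == 0) & (yhat == 0)).sum()),
    )


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricsReport:
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    accuracy = (cm.tp + cm.tn) / cm.n
    precision = cm.tp / (cm.tp + cm.fp) if (cm.tp + cm.fp) else None
    sensitivity = cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) else None
    if precision is None or sensitivity is None or (precision + sensitivity) == 0:
        f_score = None
    else:
        f_score = 2 * precision * sensitivity / (precision + sensitivity)
    return MetricsReport(accuracy=accuracy, precision=precision,
                         sensitivity=sensitivity, f_score=f_score)


def roc_auc(labels: Sequence[int], probabilities: Sequence[float]
            ) -> Tuple[np.ndarray, float]:
    """ROC curve points (fpr, tpr) and trapezoid AUC (midrank tie handling)."""
    y = np.asarray(labels).astype(int)
    p = np.asarray(probabilities, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = roc_curve(y, p)
    return np.column_stack([fpr, tpr]), float(_trapezoid_auc(fpr, tpr))


def prediction_entropy(p) -> np.ndarray | float:
    """H(p) = -(p ln p + (1-p) ln(1-p)), with 0*ln 0 = 0.

    Natural logarithm; maximal (ln 2) at p = 0.5, zero at certainty.
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -(np.where(arr > 0, arr * np.log(arr), 0.0)
              + np.where(arr < 1, (1 - arr) * np.log1p(-arr), 0.0))
    h = np.maximum(h, 0.0)
    return float(h) if np.isscalar(p) or arr.ndim == 0 else h


def iqr_outlier_mask(values: Sequence[float], factor: float = 1.5) -> np.ndarray:
    """Tukey-fence outlier mask: True where a value falls outside
    [Q1 - factor*IQR, Q3 + factor*IQR]."""
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("IQR outlier detection needs at least 4 values")
    q1, q3 = np.percentile(v, (25, 75))
    iqr = q3 - q1
    return (v < q1 - factor * iqr) | (v > q3 + factor * iqr)


def compare_wilcoxon(a: Sequence[float], b: Sequence[float], alpha: float = 0.05
                     ) -> Tuple[Optional[float], Optional[float], Optional[bool]]:
    """Two-sided Wilcoxon signed-rank test on paired scores.

    Zero differences are dropped; if every difference is zero the test is
    undefined and (None, None, None) is returned.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if np.all(a == b):
        return None, None, None
    stat, p = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided")
    return float(stat), float(p), bool(p < alpha)


def permutation_importance(
    predict_fn: Callable[[np.ndarray], np.ndarray],
    X: np.ndarray,
    y: np.ndarray,
    n_repeats: int = 10,
    seed: int = 0,
    metric: Callable[[np.ndarray, np.ndarray], float] | None = None,
    feature_names: Optional[Sequence[str]] = None,
    sectors: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Permutation feature importance: baseline metric minus the mean
    metric over ``n_repeats`` independent within-column shuffles.

    ``predict_fn`` maps a feature matrix to hard labels; the default
    metric is accuracy.  If ``sectors`` labels each feature (e.g. via
    ``grid.sector_of``), sector-aggregated scores are attached as a
    DataFrame attribute ``sector_scores``.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).ravel()
    metric = metric or (lambda yt, yp: float((yt == yp).mean()))
    rng = np.random.default_rng(seed)
    baseline = metric(y, np.asarray(predict_fn(X)).ravel())
    scores = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        drops = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(X.shape[0]), j]
            drops.append(baseline - metric(y, np.asarray(predict_fn(Xp)).ravel()))
        scores[j] = float(np.mean(drops))
    names = list(feature_names) if feature_names is not None else [
        f"x{j + 1}" for j in range(X.shape[1])
    ]
    df = pd.DataFrame({"feature": names, "importance": scores})
    df = df.sort_values("importance", ascending=False, kind="mergesort").reset_index(drop=True)
    if sectors is not None:
        sec = pd.DataFrame({"feature": names, "sector": list(sectors), "importance": scores})
        df.attrs["sector_scores"] = (
            sec.groupby("sector")["importance"].sum().sort_values(ascending=False)
        )
    return df
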