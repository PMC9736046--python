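"""Field-of-view-restricted segmentation metrics.

All pixel counting is confined to ``fov == 1``: fundus photographs are
circular images on a dark surround, and including the surround would
inflate specificity and accuracy.  AUC uses the exact Mann-Whitney rank
statistic (average ranks on ties) rather than a thresholded ROC grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = ["ConfusionCounts", "MetricsReport", "confusion_counts", "auc_score", "compute_metrics"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    acc: float
    se: float
    sp: float
    f1: float
    auc: float
    counts: ConfusionCounts | None = None

    def as_dict(self) -> dict:
        return {"ACC": self.acc, "SE": self.se, "SP": self.sp, "F1": self.f1, "AUC": self.auc}


def confusion_counts(pred: np.ndarray, gt: np.ndarray, fov: np.ndarray) -> ConfusionCounts:
    """Counts over fov==1 pixels; ``pred`` and ``gt`` binary arrays."""
    m = fov.astype(bool)
    p = pred.astype(bool)[m]
    t = gt.astype(bool)[m]
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def metrics_from_counts(c: ConfusionCounts, auc: float = float("nan")) -> MetricsReport:
    total = c.total
    acc = (c.tp + c.tn) / total if total else float("nan")
    se = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else float("nan")
    sp = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else float("nan")
    f1 = 2 * c.tp / (2 * c.tp + c.fn + c.fp) if (2 * c.tp + c.fn + c.fp) else float("nan")
    return MetricsReport(acc=acc, se=se, sp=sp, f1=f1, auc=auc, counts=c)


def auc_score(scores: np.ndarray, labels: np.ndarray) -> float:
    """Exact Mann-Whitney AUC with average ranks for tied scores.

    Returns NaN (with a warning) when only one class is present.
    """
    labels = labels.astype(bool).ravel()
    scores = np.asarray(scores, dtype=np.float64).ravel()
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        warnings.warn("AUC undefined: ground truth contains a single class")
        return float("nan")
    ranks = rankdata(scores)
    r_pos = ranks[labels].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def compute_metrics(prob_map: np.ndarray, vessel_gt: np.ndarray, fov: np.ndarray,
                    threshold: float = 0.5) -> MetricsReport:
    """Threshold ``prob_map`` and score it against ``vessel_gt`` inside the FOV."""
    if prob_map.shape != vessel_gt.shape or prob_map.shape != fov.shape:
        raise ValueError("prob_map, vessel_gt and fov must share a shape")
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    m = fov.astype(bool)
    if not m.any():
        raise ValueError("FOV mask is empty")
    pred = prob_map >= threshold
    c = confusion_counts(pred, vessel_gt, fov)
    auc = auc_score(prob_map[m], vessel_gt.astype(bool)[m])
    return metrics_from_counts(c, auc)
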