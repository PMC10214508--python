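"""Diagnostic metrics: confusion-matrix statistics, ROC/PR curves and AUCs,
bootstrap aggregation (mean +- one sample SD), and pooled relative SD.

Conventions (fixed, documented):

* a score >= threshold predicts the positive class (ties predict positive);
* a metric with a zero denominator is undefined (``NaN``) and is excluded
  from aggregation with a count, except MCC which is 0 by convention so that
  model selection on mean MCC stays total;
* ROC AUC is the trapezoidal area under the full threshold sweep, which
  equals the Mann-Whitney pair statistic with ties counted 1/2;
* PR AUC is the trapezoidal area over recall of the threshold-swept curve,
  anchored at recall 0 with the precision of the highest-threshold defined
  point (so a constant-score classifier scores the class prevalence, and a
  perfect one scores 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ConfusionMatrix",
    "MetricVector",
    "MetricSummary",
    "Curve",
    "confusion",
    "metric_vector",
    "roc_curve_auc",
    "pr_curve_auc",
    "aggregate",
    "pooled_rsd",
]

#: Names of the per-iteration metrics, in reporting order.
METRIC_NAMES = (
    "accuracy", "precision", "sensitivity", "specificity", "f1", "mcc",
    "auc_roc", "auc_pr",
)


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass
class MetricVector:
    """One iteration's metrics; undefined entries are NaN."""

    accuracy: float = math.nan
    precision: float = math.nan
    sensitivity: float = math.nan
    specificity: float = math.nan
    f1: float = math.nan
    mcc: float = math.nan
    auc_roc: float = math.nan
    auc_pr: float = math.nan

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class MetricSummary:
    """Mean and sample SD per metric over bootstrap iterations, with a count
    of iterations where the metric was undefined (and excluded)."""

    mean: dict[str, float]
    sd: dict[str, float]
    n_undefined: dict[str, int]
    n_iterations: int


@dataclass
class Curve:
    """Ordered (x, y) points of a ROC or PR curve."""

    points: np.ndarray  # shape (k, 2)
    kind: str  # "ROC" or "PR"


def confusion(labels, scores, threshold: float = 0.5) -> ConfusionMatrix:
    """Count TP/FN/FP/TN comparing ``score >= threshold`` against labels."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    if not set(np.unique(labels).tolist()) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionMatrix(
        tp=int(np.sum(pred & pos)),
        fn=int(np.sum(~pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def metric_vector(cm: ConfusionMatrix) -> MetricVector:
    """Classification metrics from a confusion matrix (AUC fields left NaN)."""
    tp, fn, fp, tn = cm.tp, cm.fn, cm.fp, cm.tn
    mcc_den = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = (tp * tn - fp * fn) / mcc_den if mcc_den > 0 else 0.0
    return MetricVector(
        accuracy=_ratio(tp + tn, cm.n),
        precision=_ratio(tp, tp + fp),
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        f1=_ratio(2 * tp, 2 * tp + fp + fn),
        mcc=mcc,
    )


def roc_curve_auc(labels, scores) -> tuple[Curve, float]:
    """ROC curve over all thresholds and its trapezoidal AUC."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = _sk_roc_curve(labels, scores, drop_intermediate=False)
    curve = Curve(np.column_stack([fpr, tpr]), kind="ROC")
    return curve, float(np.trapezoid(tpr, fpr))


def pr_curve_auc(labels, scores) -> tuple[Curve, float]:
    """Precision-recall curve over all thresholds; AUC by trapezoid over recall."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(labels == 1))
    if n_pos == 0:
        raise ValueError("PR requires at least one positive label")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_pos = (labels[order] == 1).astype(float)
    tp = np.cumsum(sorted_pos)
    predicted = np.arange(1, len(scores) + 1, dtype=float)
    # keep only the last index of each tied score block (threshold = that score)
    distinct = np.flatnonzero(np.diff(sorted_scores, append=-np.inf))
    recall = tp[distinct] / n_pos
    precision = tp[distinct] / predicted[distinct]
    # anchor at recall 0 with the first swept precision
    recall = np.concatenate([[0.0], recall])
    precision = np.concatenate([[precision[0]], precision])
    curve = Curve(np.column_stack([recall, precision]), kind="PR")
    return curve, float(np.trapezoid(precision, recall))


def aggregate(rows) -> MetricSummary:
    """Mean and sample SD (ddof=1) per metric over iterations.

    Undefined (NaN) values are excluded and counted; a metric undefined in
    every iteration stays undefined in the summary.
    """
    rows = list(rows)
    if len(rows) < 2:
        raise ValueError("aggregation needs at least two iterations")
    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    n_undef: dict[str, int] = {}
    for name in METRIC_NAMES:
        values = np.array([getattr(r, name) for r in rows], dtype=float)
        defined = values[~np.isnan(values)]
        n_undef[name] = int(np.isnan(values).sum())
        if defined.size == 0:
            mean[name] = math.nan
            sd[name] = math.nan
        else:
            mean[name] = float(defined.mean())
            sd[name] = float(defined.std(ddof=1)) if defined.size > 1 else 0.0
    return MetricSummary(mean, sd, n_undef, len(rows))


def pooled_rsd(summary: MetricSummary, metrics=METRIC_NAMES) -> float:
    """Average relative standard deviation, in percent.

    Pools ``sd/mean * 100`` across the summary's metrics, skipping metrics
    whose mean is 0 or undefined.
    """
    rsds = []
    for name in metrics:
        m, s = summary.mean.get(name), summary.sd.get(name)
        if m is None or s is None or math.isnan(m) or math.isnan(s) or m == 0:
            continue
        rsds.append(abs(s / m) * 100.0)
    if not rsds:
        raise ValueError("no metric with a defined, nonzero mean")
    return float(np.mean(rsds))
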