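"""Binary-classification evaluation quantities.

Implements the standard confusion-matrix formulas —

.. math::

    Precision = \\frac{TP}{TP+FP}, \\quad
    Recall = \\frac{TP}{TP+FN}, \\quad
    Specificity = \\frac{TN}{TN+FP},

    Accuracy = \\frac{TP+TN}{TP+TN+FP+FN}, \\quad
    MCC = \\frac{TP \\cdot TN - FP \\cdot FN}
      {\\sqrt{(TP+FP)(TP+FN)(TN+FP)(TN+FN)}}

— plus the rank-statistic ROC area (Mann-Whitney, ties averaged) and the
step-wise average precision :math:`AP = \\sum_n (R_n - R_{n-1}) P_n`.

Any metric with a zero denominator returns 0 by convention and emits a
warning (conservative choice for degenerate confusion tables).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .errors import MetricError, ValidationError

__all__ = [
    "ConfusionCounts", "EvaluationReport", "confusion", "scalar_metrics",
    "roc_auc", "pr_ap", "evaluate_scores", "summarize_reports",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts with class 1 as positive."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValidationError("confusion counts must not all be zero")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class EvaluationReport:
    """Scalar metrics plus (optionally) ROC/PR areas, all unitless."""

    accuracy: float
    precision: float
    recall: float
    specificity: float
    mcc: float
    auc_roc: float | None = None
    auc_pr: float | None = None

    METRICS = ("accuracy", "precision", "recall", "specificity", "mcc",
               "auc_roc", "auc_pr")

    def as_dict(self) -> dict[str, float | None]:
        return {m: getattr(self, m) for m in self.METRICS}


def _check_binary(values: np.ndarray, what: str) -> np.ndarray:
    arr = np.asarray(values)
    if not np.isin(arr, (0, 1)).all():
        raise ValidationError(f"{what} must be binary 0/1")
    return arr.astype(np.int64)


def confusion(labels, predictions) -> ConfusionCounts:
    """Count TP/TN/FP/FN from equal-length binary vectors."""
    y = _check_binary(labels, "labels")
    p = _check_binary(predictions, "predictions")
    if y.shape != p.shape:
        raise ValidationError(
            f"length mismatch: {y.size} labels vs {p.size} predictions"
        )
    return ConfusionCounts(
        tp=int(np.sum((y == 1) & (p == 1))),
        tn=int(np.sum((y == 0) & (p == 0))),
        fp=int(np.sum((y == 0) & (p == 1))),
        fn=int(np.sum((y == 1) & (p == 0))),
    )


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(
            f"{name}: zero denominator, returning 0 by convention",
            RuntimeWarning, stacklevel=3,
        )
        return 0.0
    return num / den


def scalar_metrics(c: ConfusionCounts) -> EvaluationReport:
    """Accuracy, precision, recall, specificity and MCC from counts."""
    tp, tn, fp, fn = c.tp, c.tn, c.fp, c.fn
    mcc_den = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return EvaluationReport(
        accuracy=_safe_ratio(tp + tn, c.total, "accuracy"),
        precision=_safe_ratio(tp, tp + fp, "precision"),
        recall=_safe_ratio(tp, tp + fn, "recall"),
        specificity=_safe_ratio(tn, tn + fp, "specificity"),
        mcc=_safe_ratio(tp * tn - fp * fn, mcc_den, "mcc"),
    )


def _check_scored(labels, scores) -> tuple[np.ndarray, np.ndarray]:
    y = _check_binary(labels, "labels")
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValidationError("labels and scores must have equal length")
    if not np.isfinite(s).all():
        raise ValidationError("scores must be finite")
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == y.size:
        raise MetricError(
            "ROC/PR areas undefined: both classes must be present"
        )
    return y, s


def roc_auc(labels, scores) -> float:
    """ROC area via the rank (Mann-Whitney) construction, ties averaged."""
    y, s = _check_scored(labels, scores)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    ranks = rankdata(s)  # average ranks on ties
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def pr_ap(labels, scores) -> float:
    """Average precision: sum of (R_n - R_{n-1}) * P_n over descending
    unique-score thresholds."""
    y, s = _check_scored(labels, scores)
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    n_pos = int(y.sum())
    tp = np.cumsum(y_sorted)
    pred_pos = np.arange(1, y.size + 1)
    # thresholds are the distinct score values: take the last index of each
    # tied block
    block_end = np.flatnonzero(np.diff(s_sorted) != 0)
    idx = np.concatenate([block_end, [y.size - 1]])
    precision = tp[idx] / pred_pos[idx]
    recall = tp[idx] / n_pos
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev_recall) * precision))


def evaluate_scores(labels, scores, threshold: float = 0.5) -> EvaluationReport:
    """Full report from probability scores: hard labels at *threshold*
    (default 0.5) plus ROC and PR areas."""
    y, s = _check_scored(labels, scores)
    report = scalar_metrics(confusion(y, (s >= threshold).astype(int)))
    report.auc_roc = roc_auc(y, s)
    report.auc_pr = pr_ap(y, s)
    return report


def summarize_reports(reports: list[EvaluationReport]
                      ) -> dict[str, tuple[float, float]]:
    """Per-metric (mean, SD) over per-fold reports (population SD, matching
    the mean +/- SD convention of cross-validation tables)."""
    if not reports:
        raise ValidationError("no reports to summarize")
    out = {}
    for m in EvaluationReport.METRICS:
        vals = [getattr(r, m) for r in reports]
        if any(v is None for v in vals):
            continue
        arr = np.asarray(vals, dtype=float)
        out[m] = (float(arr.mean()), float(arr.std()))
    return out
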