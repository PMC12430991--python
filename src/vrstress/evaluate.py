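"""Evaluation metrics: confusion matrices, per-class scores, ROC/AUC,
Pearson correlation and summary statistics.

The one-vs-rest ROC sweep groups tied scores into a single step, so the
trapezoidal AUC equals the Mann-Whitney rank statistic
(pairs won + half ties) / (n_pos * n_neg) exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats


@dataclass
class ConfusionMatrix:
    """Counts with rows = true labels, columns = predicted labels."""

    labels: tuple
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class ClassMetrics:
    precision: dict
    recall: dict
    f1: dict
    accuracy: float


@dataclass
class RocResult:
    """Per-class one-vs-rest ROC points and AUC (None where undefined)."""

    points: dict  # label -> (fpr array, tpr array)
    auc: dict     # label -> float or None


def confusion(
    y_true: Sequence, y_pred: Sequence, labels: Optional[Sequence] = None
) -> ConfusionMatrix:
    y_true, y_pred = list(y_true), list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError(f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted")
    if labels is None:
        labels = sorted(set(y_true) | set(y_pred))
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for yt, yp in zip(y_true, y_pred):
        if yt not in index or yp not in index:
            raise ValueError(f"label {yt if yt not in index else yp!r} not in {labels}")
        counts[index[yt], index[yp]] += 1
    return ConfusionMatrix(labels=tuple(labels), counts=counts)


def class_metrics(cm: ConfusionMatrix) -> ClassMetrics:
    """Per-class precision/recall/F1 and overall accuracy.

    An empty row or column yields 0 for the affected metric; F1 is the
    harmonic mean (0 when precision and recall are both 0).
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    diag = np.diag(cm.counts)
    col = cm.counts.sum(axis=0)
    row = cm.counts.sum(axis=1)
    precision, recall, f1 = {}, {}, {}
    for i, lab in enumerate(cm.labels):
        p = diag[i] / col[i] if col[i] else 0.0
        r = diag[i] / row[i] if row[i] else 0.0
        precision[lab] = float(p)
        recall[lab] = float(r)
        f1[lab] = float(2 * p * r / (p + r)) if (p + r) else 0.0
    return ClassMetrics(
        precision=precision, recall=recall, f1=f1,
        accuracy=float(diag.sum() / cm.total),
    )


def _binary_roc(scores: np.ndarray, positive: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Threshold-sweep ROC with tied scores grouped into one step."""
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], positive[order]
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    # group boundaries where the score changes
    distinct = np.flatnonzero(np.diff(s)) + 1
    edges = np.concatenate([distinct, [s.size]])
    tp = np.cumsum(y)[edges - 1]
    fp = np.cumsum(~y)[edges - 1]
    tpr = np.concatenate([[0.0], tp / n_pos])
    fpr = np.concatenate([[0.0], fp / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def roc_ovr(
    scores: dict, y_true: Sequence, labels: Optional[Sequence] = None
) -> RocResult:
    """One-vs-rest ROC per class from per-class continuous scores.

    ``scores[label]`` ranks items as that class; a class absent from the
    truth (or covering all of it) has an undefined AUC, reported as None.
    """
    y = np.asarray(list(y_true))
    labels = tuple(labels) if labels is not None else tuple(scores.keys())
    points, auc = {}, {}
    for lab in labels:
        sc = np.asarray(scores[lab], dtype=float)
        if sc.size != y.size:
            raise ValueError(f"scores for {lab!r} have length {sc.size}, truth {y.size}")
        pos = y == lab
        if pos.all() or not pos.any():
            points[lab], auc[lab] = None, None
            continue
        fpr, tpr, a = _binary_roc(sc, pos)
        points[lab] = (fpr, tpr)
        auc[lab] = a
    return RocResult(points=points, auc=auc)


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson r with the two-sided t-distribution p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("pearson needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class SummaryStats:
    median: float
    mean: float
    q1: float
    q3: float

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


def summary_stats(values: Sequence[float]) -> SummaryStats:
    """Median (midpoint for even n), mean, and linearly interpolated quartiles."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    return SummaryStats(
        median=float(np.median(v)),
        mean=float(np.mean(v)),
        q1=float(np.percentile(v, 25)),
        q3=float(np.percentile(v, 75)),
    )
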