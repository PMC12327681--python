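"""Metrics and statistics: confusion matrices, macro-averaged scores, the
exact paired Wilcoxon signed-rank test, bootstrap confidence intervals and
relative-improvement reporting.

The Wilcoxon test is computed by full enumeration of all sign assignments —
with 6 cross-validation folds the normal approximation is meaningless and the
exact two-sided floor is 2/64 = 0.03125.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = ["MetricsReport", "confusion_matrix", "macro_metrics",
           "wilcoxon_exact_paired", "bootstrap_ci", "relative_improvement"]


@dataclass
class MetricsReport:
    """Aggregated evaluation output for one experiment."""

    fold_metrics: list[dict] = field(default_factory=list)
    holdout_confusion: np.ndarray | None = None
    holdout_metrics: dict | None = None
    p_values: dict[str, float] = field(default_factory=dict)
    bootstrap_cis: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "fold_metrics": self.fold_metrics,
            "holdout_confusion": (None if self.holdout_confusion is None
                                  else self.holdout_confusion.tolist()),
            "holdout_metrics": self.holdout_metrics,
            "p_values": self.p_values,
            "bootstrap_cis": {k: list(v) for k, v in self.bootstrap_cis.items()},
        }


def confusion_matrix(y_true, y_pred, n_classes: int) -> np.ndarray:
    """Entry (i, j) counts true class i predicted as class j."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    for name, y in (("y_true", y_true), ("y_pred", y_pred)):
        if y.size and (y.min() < 0 or y.max() >= n_classes):
            raise ValueError(f"{name} contains labels outside [0, {n_classes})")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def macro_metrics(cm: np.ndarray) -> dict:
    """Per-class precision/recall/F1 plus macro averages.

    ``accuracy`` is the standard trace/total; ``macro_accuracy`` is the
    unweighted mean of per-class recalls (the form some multi-class reports
    label simply "Accuracy").  Classes with a zero denominator contribute 0
    to the macro averages.
    """
    cm = np.asarray(cm, dtype=np.float64)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1] or cm.size == 0:
        raise ValueError("confusion matrix must be square and nonempty")
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(cm)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        pr = precision + recall
        f1 = np.where(pr > 0, 2 * precision * recall / np.where(pr > 0, pr, 1.0), 0.0)
    if np.any((tp + fp == 0) | (tp + fn == 0)):
        logger.debug("macro_metrics: zero-denominator class contributes 0")
    return {
        "accuracy": float(tp.sum() / total),
        "macro_accuracy": float(recall.mean()),
        "macro_f1": float(f1.mean()),
        "macro_precision": float(precision.mean()),
        "macro_recall": float(recall.mean()),
        "per_class": {
            "precision": precision.tolist(),
            "recall": recall.tolist(),
            "f1": f1.tolist(),
        },
    }


def wilcoxon_exact_paired(a, b) -> float:
    """Exact two-sided paired Wilcoxon signed-rank p-value.

    Zero differences are discarded before ranking; tied absolute differences
    receive mid-ranks.  The p-value enumerates all 2^k sign assignments of
    the remaining k differences, so it is exact for the small k used here.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("inputs must be equal-length nonempty 1-D arrays")
    d = a - b
    d = d[d != 0]
    k = d.size
    if k == 0:
        logger.warning("wilcoxon_exact_paired: all differences are zero; p = 1")
        return 1.0
    ranks = rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    total = ranks.sum()
    # two-sided: W and its mirror total - W
    w_low, w_high = min(w_plus, total - w_plus), max(w_plus, total - w_plus)
    count = 0
    for signs in itertools.product((0, 1), repeat=k):
        w = sum(r for s, r in zip(signs, ranks) if s)
        if w <= w_low + 1e-12 or w >= w_high - 1e-12:
            count += 1
    return min(1.0, count / 2 ** k)


def bootstrap_ci(values, n_boot: int = 1000, level: float = 0.95,
                 seed: int = 0) -> tuple[float, float]:
    """Percentile bootstrap interval for the mean of ``values``."""
    values = np.asarray(values, dtype=np.float64)
    if values.size < 2:
        raise ValueError("need at least 2 values for a bootstrap interval")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def relative_improvement(baseline: float, improved: float) -> float:
    """Percent change 100 * (improved - baseline) / baseline, to 2 decimals."""
    if baseline <= 0:
        raise ValueError(f"baseline must be positive, got {baseline}")
    return round(100.0 * (improved - baseline) / baseline, 2)
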