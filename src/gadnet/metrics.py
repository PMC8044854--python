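"""Classification metrics and the paired statistical comparison.

Per-class precision, recall and F1 are computed from confusion counts with
each class treated as the positive class in turn; the headline metric is the
weighted F1 score, the class-size-weighted mean of the two per-class F1
scores. Model comparisons use the classical paired t-test over fold-wise
scores with Bonferroni adjustment across simultaneous comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN with respect to a designated positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_counts(predicted, truth, positive_class) -> ConfusionCounts:
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError(f"length mismatch: {predicted.shape} vs {truth.shape}")
    pred_pos = predicted == positive_class
    true_pos = truth == positive_class
    return ConfusionCounts(
        tp=int(np.sum(pred_pos & true_pos)),
        fp=int(np.sum(pred_pos & ~true_pos)),
        tn=int(np.sum(~pred_pos & ~true_pos)),
        fn=int(np.sum(~pred_pos & true_pos)),
    )


def precision_recall_f1(counts: ConfusionCounts) -> dict:
    """precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = harmonic mean.

    Undefined 0/0 ratios are reported as 0.0 with ``degenerate=True``.
    """
    degenerate = False
    if counts.tp + counts.fp == 0:
        precision, degenerate = 0.0, True
    else:
        precision = counts.tp / (counts.tp + counts.fp)
    if counts.tp + counts.fn == 0:
        recall, degenerate = 0.0, True
    else:
        recall = counts.tp / (counts.tp + counts.fn)
    if precision + recall == 0.0:
        f1 = 0.0
        degenerate = degenerate or counts.tp == 0
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return {"precision": precision, "recall": recall, "f1": f1, "degenerate": degenerate}


def weighted_f1(f1_by_class: dict, n_by_class: dict) -> float:
    """Class-size-weighted mean of per-class F1 scores."""
    total = sum(n_by_class.values())
    if total == 0:
        raise ValueError("at least one class must have members")
    return sum(n_by_class[c] * f1_by_class[c] for c in n_by_class) / total


def score_predictions(predicted, truth, classes=(0, 1)) -> dict:
    """Per-class precision/recall/F1 plus the weighted F1 for one evaluation."""
    per_class = {}
    n_by_class = {}
    for c in classes:
        counts = confusion_counts(predicted, truth, c)
        per_class[c] = precision_recall_f1(counts)
        n_by_class[c] = int(np.sum(np.asarray(truth) == c))
    wf1 = weighted_f1({c: per_class[c]["f1"] for c in classes}, n_by_class)
    return {"per_class": per_class, "n_by_class": n_by_class, "weighted_f1": wf1}


def paired_t_test(scores_a, scores_b) -> tuple[float, int, float]:
    """Classical paired t-test on fold-wise score differences.

    Returns (t, df, p) with df = n - 1. Zero-variance differences are handled
    explicitly: all-zero differences give (0, df, 1); constant nonzero
    differences give (+/-inf, df, 0).
    """
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired score vectors must be 1-D and equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least two paired scores")
    d = a - b
    sd = d.std(ddof=1)
    df = n - 1
    if sd == 0.0:
        if d.mean() == 0.0:
            return 0.0, df, 1.0
        return float(np.sign(d.mean()) * np.inf), df, 0.0
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), df, float(p)


def bonferroni_adjust(p_values, m: int | None = None) -> list[float]:
    """p_adj = min(1, m * p); m defaults to the number of p-values."""
    p_values = list(p_values)
    m = m if m is not None else len(p_values)
    if m < 1:
        raise ValueError("m must be >= 1")
    return [min(1.0, m * p) for p in p_values]
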