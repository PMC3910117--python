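"""Evaluation metrics: sensitivity/specificity sweeps, ARI, and AARI.

The screen is scored as a binary classifier over a sweep of F-statistic
thresholds (a profile is called "time-course" when its F exceeds the
threshold).  Clustering is scored against ground-truth labels with the
Hubert-Arabie adjusted Rand index and, across repeated runs from random
starts, its average (AARI), which measures quality and stability together.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

__all__ = [
    "ConfusionCounts",
    "SweepResult",
    "UndefinedMetricError",
    "sensitivity_specificity",
    "threshold_sweep",
    "adjusted_rand_index",
    "aari",
]


class UndefinedMetricError(ValueError):
    """A metric's denominator is zero (a class is absent)."""


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts: positives are time-course profiles."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(
        cls, predicted: Sequence[bool], truth: Sequence[bool]
    ) -> "ConfusionCounts":
        predicted = np.asarray(predicted, dtype=bool)
        truth = np.asarray(truth, dtype=bool)
        if predicted.shape != truth.shape:
            raise ValueError("predicted and truth have different lengths")
        return cls(
            tp=int(np.sum(predicted & truth)),
            fp=int(np.sum(predicted & ~truth)),
            tn=int(np.sum(~predicted & ~truth)),
            fn=int(np.sum(~predicted & truth)),
        )


def sensitivity_specificity(counts: ConfusionCounts) -> tuple[float, float]:
    """(sensitivity, specificity) = (tp/(tp+fn), tn/(tn+fp))."""
    if counts.tp + counts.fn == 0:
        raise UndefinedMetricError("no positive profiles: sensitivity undefined")
    if counts.tn + counts.fp == 0:
        raise UndefinedMetricError("no negative profiles: specificity undefined")
    return (
        counts.tp / (counts.tp + counts.fn),
        counts.tn / (counts.tn + counts.fp),
    )


@dataclasses.dataclass(frozen=True)
class SweepResult:
    """Sensitivity/specificity evaluated at every distinct score threshold.

    ``best_threshold`` maximizes min(sensitivity, specificity) — the
    operating point at which both error rates are balanced; ties go to the
    smallest threshold.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    best_threshold: float
    best_sensitivity: float
    best_specificity: float

    @property
    def best_min(self) -> float:
        return min(self.best_sensitivity, self.best_specificity)


def threshold_sweep(
    f_values: Sequence[float], truth_labels: Sequence[bool]
) -> SweepResult:
    """Sweep every distinct F value as a classification threshold.

    A profile is predicted time-course when its F strictly exceeds the
    threshold.  As the threshold rises, sensitivity is non-increasing and
    specificity non-decreasing.
    """
    f = np.asarray(f_values, dtype=float)
    truth = np.asarray(truth_labels, dtype=bool)
    if f.shape != truth.shape or f.size == 0:
        raise ValueError("f_values and truth_labels must be equal-length, nonempty")
    n_pos = int(truth.sum())
    n_neg = truth.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("both classes must be present for a sweep")

    order = np.argsort(f, kind="stable")
    f_sorted = f[order]
    truth_sorted = truth[order]
    # cumulative class counts with score <= each sorted position
    cum_pos = np.cumsum(truth_sorted)
    cum_neg = np.cumsum(~truth_sorted)
    thresholds, last_idx = np.unique(f_sorted, return_index=True)
    # index of the last occurrence of each distinct value
    last_idx = np.append(last_idx[1:], f_sorted.size) - 1
    # predict positive when F > threshold
    tp = n_pos - cum_pos[last_idx]
    fp = n_neg - cum_neg[last_idx]
    sens = tp / n_pos
    spec = (n_neg - fp) / n_neg
    best = int(np.argmax(np.minimum(sens, spec)))
    return SweepResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        best_threshold=float(thresholds[best]),
        best_sensitivity=float(sens[best]),
        best_specificity=float(spec[best]),
    )


def _comb2(n: np.ndarray) -> np.ndarray:
    n = n.astype(np.int64)
    return n * (n - 1) // 2


def contingency_table(
    labels_u: Sequence[int], labels_v: Sequence[int]
) -> np.ndarray:
    """r x s table of co-occurrence counts between two labelings."""
    u = np.asarray(labels_u)
    v = np.asarray(labels_v)
    if u.shape != v.shape:
        raise ValueError("label vectors have different lengths")
    _, ui = np.unique(u, return_inverse=True)
    _, vi = np.unique(v, return_inverse=True)
    table = np.zeros((ui.max() + 1, vi.max() + 1), dtype=np.int64)
    np.add.at(table, (ui, vi), 1)
    return table


def adjusted_rand_index(
    labels_u: Sequence[int], labels_v: Sequence[int]
) -> float:
    """Hubert-Arabie adjusted Rand index between two partitions.

    ARI = (sum_ij C(n_ij,2) - E) / (M - E) with
    E = sum_i C(n_i.,2) * sum_j C(n_.j,2) / C(N,2) and
    M = [sum_i C(n_i.,2) + sum_j C(n_.j,2)] / 2.

    Symmetric, invariant under relabeling, at most 1 (identical
    partitions), and 0 in expectation for independent random partitions.
    When both partitions are the single trivial cluster (M = E) the
    partitions agree perfectly and 1 is returned by convention.
    """
    table = contingency_table(labels_u, labels_v)
    n = int(table.sum())
    if n < 2:
        raise ValueError("need at least 2 objects")
    sum_ij = int(_comb2(table).sum())
    sum_i = int(_comb2(table.sum(axis=1)).sum())
    sum_j = int(_comb2(table.sum(axis=0)).sum())
    total_pairs = n * (n - 1) // 2
    expected = sum_i * sum_j / total_pairs
    max_index = 0.5 * (sum_i + sum_j)
    if max_index == expected:
        return 1.0
    return (sum_ij - expected) / (max_index - expected)


def aari(
    label_sets: Sequence[Sequence[int]], reference_labels: Sequence[int]
) -> float:
    """Average ARI of repeated clustering runs against a reference partition."""
    if len(label_sets) == 0:
        raise ValueError("need at least one label set")
    return float(
        np.mean([adjusted_rand_index(labels, reference_labels) for labels in label_sets])
    )
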