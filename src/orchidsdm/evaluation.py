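"""Model evaluation: AUC, TSS, Kappa and paired strategy comparisons.

AUC is the rank-based (Mann-Whitney) probability that a random presence is
scored above a random (pseudo-)absence, with half credit for ties.  TSS is
sensitivity + specificity - 1 and Kappa the chance-corrected agreement; both
live in [-1, 1] and are reported at the metric-maximizing threshold (the
fixed-0.5 values can be computed by passing the threshold explicitly).
Strategies are compared by a paired two-sided t-test over runs sharing
(pseudo-absence set, repeat) labels, significant at p < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def at_threshold(
        cls, scores: np.ndarray, labels: np.ndarray, threshold: float
    ) -> "ConfusionMatrix":
        scores = np.asarray(scores, dtype=float)
        labels = np.asarray(labels).astype(bool)
        pred = scores > threshold
        return cls(
            tp=int((pred & labels).sum()),
            fp=int((pred & ~labels).sum()),
            tn=int((~pred & ~labels).sum()),
            fn=int((~pred & labels).sum()),
        )


@dataclass
class MetricResult:
    """One run's scores; run identity mirrors the strategy naming."""

    dataset: str
    algorithm: str
    pa_set: int
    repeat: int
    hi_on: bool
    auc: float
    tss: float
    kappa: float
    tss_threshold: float
    kappa_threshold: float


@dataclass
class ComparisonResult:
    group_a: str
    group_b: str
    mean_diff: float
    t_statistic: float
    p_value: float
    significant: bool


def auc(scores, labels) -> float:
    """Rank-based AUC with half credit for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined with a single class")
    ranks = stats.rankdata(scores, method="average")
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def tss(cm: ConfusionMatrix) -> float:
    """True skill statistic: sensitivity + specificity - 1."""
    if cm.tp + cm.fn == 0 or cm.tn + cm.fp == 0:
        raise ValueError("TSS undefined with an empty class margin")
    sens = cm.tp / (cm.tp + cm.fn)
    spec = cm.tn / (cm.tn + cm.fp)
    return sens + spec - 1.0


def kappa(cm: ConfusionMatrix) -> float:
    """Cohen's kappa from the 2x2 confusion matrix."""
    n = cm.n
    if n == 0:
        raise ValueError("kappa undefined on an empty matrix")
    po = (cm.tp + cm.tn) / n
    pe = ((cm.tp + cm.fn) * (cm.tp + cm.fp) + (cm.tn + cm.fp) * (cm.tn + cm.fn)) / n**2
    if pe == 1.0:
        warnings.warn("degenerate margins: chance agreement = 1; kappa set to 0")
        return 0.0
    return (po - pe) / (1.0 - pe)


def best_threshold_metric(scores, labels, metric) -> tuple[float, float]:
    """Maximize a confusion-matrix metric over all distinct score cut-points.

    Candidates are the distinct scores plus 0.5 (so the fixed-0.5 value is
    never beaten silently); ties take the lowest threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    candidates = np.unique(np.append(scores, 0.5))
    best_t, best_v = None, -np.inf
    for t in candidates:
        cm = ConfusionMatrix.at_threshold(scores, labels, t)
        try:
            v = metric(cm)
        except ValueError:
            continue
        if v > best_v:
            best_t, best_v = float(t), float(v)
    return best_t, best_v


def compare_strategies(
    results_a: list[MetricResult],
    results_b: list[MetricResult],
    metric: str = "auc",
    alpha: float = 0.05,
    label_a: str = "a",
    label_b: str = "b",
) -> ComparisonResult:
    """Paired two-sided t-test over runs matched by (pa_set, repeat)."""
    key = lambda r: (r.pa_set, r.repeat)
    a_map = {key(r): getattr(r, metric) for r in results_a}
    b_map = {key(r): getattr(r, metric) for r in results_b}
    shared = sorted(set(a_map) & set(b_map))
    orphans = sorted(set(a_map) ^ set(b_map))
    if orphans:
        raise ValueError(f"unpairable runs: {orphans}")
    if len(shared) < 3:
        raise ValueError("need at least 3 paired runs")
    a = np.array([a_map[k] for k in shared])
    b = np.array([b_map[k] for k in shared])
    d = a - b
    if np.allclose(d, 0.0):
        return ComparisonResult(label_a, label_b, 0.0, 0.0, 1.0, False)
    if np.std(d, ddof=1) <= 1e-12 * max(1.0, float(np.abs(d).max())):
        warnings.warn("zero variance in paired differences; p-value degenerate")
        return ComparisonResult(
            label_a, label_b, float(d.mean()), np.inf * np.sign(d.mean()), 0.0, True
        )
    t_stat, p = stats.ttest_rel(a, b)
    return ComparisonResult(
        label_a, label_b, float(d.mean()), float(t_stat), float(p), bool(p < alpha)
    )
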