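"""Diagnostic-accuracy and comparison statistics.

2x2 contingency machinery (sensitivity/specificity/PPV/NPV), the two-tailed
Fisher exact test, the exact Mann-Whitney test, and ROC threshold selection
by the Youden index. Exact tests are delegated to scipy; the surrounding
conventions (two-sided Fisher by summing hypergeometric probabilities no
larger than the observed table's, percent reporting to one decimal with
half-away-from-zero rounding, low-threshold tie-breaks on the ROC) are fixed
here so results are reproducible across backends.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
from scipy import stats as sps


def round_percent(numerator: float, denominator: float) -> float | None:
    """Percent to one decimal, half away from zero; None if denominator 0."""
    if denominator == 0:
        return None
    pct = Decimal(100 * numerator) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionTable:
    """Standard 2x2 diagnostic contingency table.

    Metrics are reported in percent to one decimal; a metric whose
    denominator is zero is undefined and reported as None.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")
        if self.n < 1:
            raise ValueError("table must contain at least one observation")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def sensitivity(self) -> float | None:
        return round_percent(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float | None:
        return round_percent(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float | None:
        return round_percent(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float | None:
        return round_percent(self.tn, self.tn + self.fn)

    @property
    def accuracy(self) -> float | None:
        return round_percent(self.tp + self.tn, self.n)

    def as_array(self) -> np.ndarray:
        return np.array([[self.tp, self.fn], [self.fp, self.tn]])


def confusion(pred: Sequence, truth: Sequence, positive) -> ConfusionTable:
    """Build a 2x2 table from paired predicted and true labels."""
    if len(pred) != len(truth):
        raise ValueError("pred and truth must have equal length")
    if len(pred) == 0:
        raise ValueError("need at least one observation")
    tp = fp = fn = tn = 0
    for p, t in zip(pred, truth):
        if p == positive:
            if t == positive:
                tp += 1
            else:
                fp += 1
        else:
            if t == positive:
                fn += 1
            else:
                tn += 1
    return ConfusionTable(tp, fp, fn, tn)


def fisher_exact_2x2(table: Sequence[Sequence[int]] | np.ndarray) -> float:
    """Two-tailed Fisher exact test for a 2x2 table.

    Two-sided p is the sum of hypergeometric probabilities, over all tables
    with the observed margins, that do not exceed the observed table's
    probability (the mainstream "probability method" convention).
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    if arr.sum() < 1:
        raise ValueError("table must contain at least one observation")
    return float(sps.fisher_exact(arr, alternative="two-sided").pvalue)


class MwMethod(str, enum.Enum):
    EXACT = "exact"
    NORMAL_APPROX = "normal_approx"


#: Combined sample size up to which the exact null distribution is enumerated.
EXACT_ENUMERATION_BOUND = 25


def mann_whitney_exact(x: Sequence[float], y: Sequence[float],
                       exact_bound: int = EXACT_ENUMERATION_BOUND
                       ) -> tuple[float, MwMethod]:
    """Two-sided Mann-Whitney test; exact for small tie-free samples.

    Returns ``(p, method)``. The exact null distribution is used when the
    combined sample size is at most ``exact_bound`` and the data are tie-free;
    otherwise the normal approximation with tie correction is used. The
    method actually applied is always recorded in the return value.
    """
    x, y = list(x), list(y)
    if not x or not y:
        raise ValueError("both samples must be non-empty")
    pooled = x + y
    ties = len(set(pooled)) < len(pooled)
    if len(pooled) <= exact_bound and not ties:
        method = MwMethod.EXACT
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        method = MwMethod.NORMAL_APPROX
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(min(res.pvalue, 1.0)), method


@dataclass
class RocResult:
    """ROC points, trapezoidal AUC and the Youden-optimal threshold.

    ``points`` holds (threshold, sensitivity, specificity) with sensitivity
    and specificity as fractions in [0, 1]; a score is called positive when
    it is >= the threshold.
    """

    points: list[tuple[float, float, float]]
    auc: float
    optimal_threshold: float
    criterion: str = "youden"

    @property
    def youden_index(self) -> float:
        sens, spec = next((s, p) for t, s, p in self.points
                          if t == self.optimal_threshold)
        return sens + spec - 1.0

    def plot(self, ax=None):
        """Plot the ROC curve, marking the optimal threshold."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        fpr = [1 - spec for _, _, spec in self.points]
        tpr = [sens for _, sens, _ in self.points]
        ax.plot(fpr, tpr, drawstyle="steps-post", label=f"AUC = {self.auc:.3f}")
        t, s, p = next(pt for pt in self.points if pt[0] == self.optimal_threshold)
        ax.plot(1 - p, s, "s", color="purple",
                label=f"threshold = {self.optimal_threshold:.3g}")
        ax.plot([0, 1], [0, 1], ":", color="grey")
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend()
        return ax


def roc_threshold(scores: Sequence[float], labels: Sequence[int],
                  criterion: str = "youden") -> RocResult:
    """ROC analysis with Youden-optimal threshold selection.

    Candidate thresholds are the midpoints between consecutive distinct
    sorted scores plus -inf/+inf sentinels; prediction is positive when
    score >= threshold. The optimal threshold maximizes
    sensitivity + specificity - 1; ties break toward the lowest threshold
    (favoring sensitivity, the screening-appropriate choice). AUC is the
    trapezoidal area under the (FPR, TPR) curve.
    """
    if criterion != "youden":
        raise ValueError(f"unsupported criterion: {criterion}")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-d sequences")
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    distinct = np.unique(scores)
    thresholds = np.concatenate(
        [[-np.inf], (distinct[:-1] + distinct[1:]) / 2.0, [np.inf]])
    points = []
    for t in thresholds:
        pred = scores >= t
        sens = float(np.sum(pred & (labels == 1)) / n_pos)
        spec = float(np.sum(~pred & (labels == 0)) / n_neg)
        points.append((float(t), sens, spec))
    best = max(points, key=lambda p: (p[1] + p[2] - 1.0, -p[0]))
    fpr = np.array([1 - spec for _, _, spec in points])
    tpr = np.array([sens for _, sens, _ in points])
    order = np.lexsort((tpr, fpr))  # vertical runs traversed upward
    auc = float(np.trapezoid(tpr[order], fpr[order]))
    return RocResult(points, auc, best[0], criterion)
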