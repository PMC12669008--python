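"""Confusion counts, ROC curves, and diagnostic accuracy metrics.

Decision rule
-------------
A record is predicted positive when its score is **greater than or equal
to** the threshold.  With this rule the threshold t = 0 yields the
all-positive corner of the ROC curve and every observed score is itself
an attainable cut-off.  A strict ``score > t`` variant is available via
``strict=True`` wherever counts are formed.

Candidate thresholds for a sweep are the unique observed scores plus a
sentinel just above the maximum (the all-negative corner), so the curve
is exact on finite data; dense grids are an explicit option elsewhere.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .cohort import ScoredCohort

__all__ = [
    "ConfusionCounts",
    "DiagnosticMetrics",
    "RocCurve",
    "UndefinedMetricWarning",
    "confusion_at_threshold",
    "metrics",
    "roc_curve",
]


class UndefinedMetricWarning(UserWarning):
    """A ratio metric was undefined (empty class) and reported as NaN."""


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN counts produced at one decision threshold."""

    tp: int
    fp: int
    tn: int
    fn: int
    threshold: float

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp


@dataclasses.dataclass(frozen=True)
class DiagnosticMetrics:
    """Sensitivity, specificity, accuracy; NaN marks an undefined ratio."""

    se: float
    sp: float
    acc: float

    def rounded(self, ndigits: int = 2) -> "DiagnosticMetrics":
        r = lambda v: v if np.isnan(v) else round(v, ndigits)
        return DiagnosticMetrics(r(self.se), r(self.sp), r(self.acc))


@dataclasses.dataclass(frozen=True)
class RocCurve:
    """ROC sweep: strictly decreasing thresholds with (FPR, TPR) and AUC.

    ``thresholds[0]`` is a sentinel above every observed score (the (0, 0)
    corner); the remaining entries are the unique observed scores in
    decreasing order, ending at the (1, 1) corner.
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def candidate_thresholds(self) -> np.ndarray:
        """Observed-score cut-offs (the sweep without the sentinel)."""
        return self.thresholds[1:]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _check_threshold(t: float) -> float:
    t = float(t)
    if not 0.0 <= t <= 1.0 or np.isnan(t):
        raise ValueError(f"threshold must lie in [0, 1], got {t!r}")
    return t


def sweep_counts(
    cohort: ScoredCohort, thresholds: np.ndarray, *, strict: bool = False
):
    """Vectorized TP/FP/TN/FN counts at each of an array of thresholds.

    Returns four integer arrays aligned with ``thresholds``.  The decision
    rule is ``score >= t`` (or ``score > t`` when ``strict``).
    """
    thresholds = np.asarray(thresholds, dtype=float)
    pos = np.sort(cohort.positive_scores())
    neg = np.sort(cohort.negative_scores())
    side = "right" if strict else "left"
    tp = pos.size - np.searchsorted(pos, thresholds, side=side)
    fp = neg.size - np.searchsorted(neg, thresholds, side=side)
    fn = pos.size - tp
    tn = neg.size - fp
    return tp, fp, tn, fn


def confusion_at_threshold(
    cohort: ScoredCohort, t: float, *, strict: bool = False
) -> ConfusionCounts:
    """Confusion counts for the cohort at decision threshold ``t``."""
    t = _check_threshold(t)
    tp, fp, tn, fn = sweep_counts(cohort, np.array([t]), strict=strict)
    return ConfusionCounts(int(tp[0]), int(fp[0]), int(tn[0]), int(fn[0]), t)


def metrics(counts: ConfusionCounts) -> DiagnosticMetrics:
    """Sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy (TP+TN)/n.

    A ratio with an empty denominator (no positives, or no negatives) is
    reported as NaN with an :class:`UndefinedMetricWarning`, never as a
    silent 0, so batch reports survive degenerate strata.
    """
    if counts.n < 1:
        raise ValueError("confusion counts are empty")
    if counts.n_pos > 0:
        se = counts.tp / counts.n_pos
    else:
        warnings.warn(
            "sensitivity undefined: no positive records", UndefinedMetricWarning
        )
        se = float("nan")
    if counts.n_neg > 0:
        sp = counts.tn / counts.n_neg
    else:
        warnings.warn(
            "specificity undefined: no negative records", UndefinedMetricWarning
        )
        sp = float("nan")
    acc = (counts.tp + counts.tn) / counts.n
    return DiagnosticMetrics(se, sp, acc)


def roc_curve(cohort: ScoredCohort, *, strict: bool = False) -> RocCurve:
    """ROC curve over the unique observed scores, with trapezoidal AUC.

    Requires at least one record of each class; AUC is undefined
    otherwise.  Ties between positive and negative scores contribute half
    a concordant pair to the AUC, which the trapezoid over the step curve
    produces automatically under the ``>=`` rule.
    """
    if cohort.n_pos == 0 or cohort.n_neg == 0:
        raise ValueError(
            "ROC/AUC undefined for a single-class cohort "
            f"(n_pos={cohort.n_pos}, n_neg={cohort.n_neg})"
        )
    unique_desc = np.unique(cohort.scores)[::-1]
    sentinel = np.nextafter(unique_desc[0], np.inf)
    thresholds = np.concatenate(([sentinel], unique_desc))
    tp, fp, _, _ = sweep_counts(cohort, thresholds, strict=strict)
    tpr = tp / cohort.n_pos
    fpr = fp / cohort.n_neg
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds, fpr, tpr, auc)
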