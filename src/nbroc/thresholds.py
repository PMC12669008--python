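"""Decision-threshold selection strategies for screening classifiers.

Four families of strategies are implemented:

1. **Closest to the top-left corner** — minimize the Euclidean distance
   d = sqrt((1 − Se)² + FPR²) from (0, 1) to the ROC curve.
2. **Youden index** — maximize J = Se + Sp − 1.
3. **Fixed sensitivity (or specificity)** — maximize the complementary
   metric subject to a floor on the fixed one.
4. **Net-benefit curve intersection** — sweep a common threshold axis t
   and locate the crossing of two net-benefit curves:

   .. math::

      NB_0(t) = \\frac{TP(t)}{n} - \\frac{TN(t)}{n}\\,\\frac{t}{1-t},
      \\qquad
      NB_1(t) = \\frac{FP(t)}{n} - \\frac{FN(t)}{n}\\,\\frac{t}{1-t}.

   NB0 rewards correct classification (weighted true negatives traded
   against true positives); NB1 tracks the two error types.  The
   x-coordinate of their intersection is taken as the decision threshold.
   Both weights default to the sweep value t; fixed weights p0, p1 derived
   from an explicit loss/profit ratio (``probability_threshold_from_losses``)
   may be supplied instead.

The classical decision-curve net benefit TP/n − FP/n · pt/(1 − pt) is
also provided (:func:`vickers_net_benefit`) for comparison.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .cohort import ScoredCohort
from .roc import (
    ConfusionCounts,
    DiagnosticMetrics,
    RocCurve,
    confusion_at_threshold,
    metrics,
    roc_curve,
    sweep_counts,
)

__all__ = [
    "GRID_EPS",
    "LossProfile",
    "NetBenefitCurves",
    "NoIntersectionError",
    "MultipleIntersectionsWarning",
    "ThresholdSelection",
    "closest_topleft_threshold",
    "default_nb_grid",
    "fixed_sensitivity_threshold",
    "fixed_specificity_threshold",
    "net_benefit_curves",
    "nb_intersection_threshold",
    "probability_threshold_from_losses",
    "vickers_net_benefit",
    "youden_threshold",
]

#: Guard against the diverging weight t/(1-t): grids stop at 1 - GRID_EPS.
GRID_EPS = 1e-3


class NoIntersectionError(RuntimeError):
    """The NB0 and NB1 curves do not cross on the evaluated grid."""


class MultipleIntersectionsWarning(UserWarning):
    """More than one NB0/NB1 crossing was found; the smallest-t one is used."""


@dataclasses.dataclass(frozen=True)
class LossProfile:
    """Relative losses L (treating healthy) and profits P (treating sick)."""

    L: float
    P: float

    def __post_init__(self) -> None:
        if not (self.L > 0 and self.P > 0):
            raise ValueError(
                f"losses and profits must be positive, got L={self.L}, P={self.P}"
            )


def probability_threshold_from_losses(profile: LossProfile) -> float:
    """Threshold probability pt = L/(L+P), i.e. pt/(1−pt) = L/P.

    This is how a cost-benefit judgement (harm of a false positive
    relative to the value of a true positive) becomes a probability
    cut-off in decision-curve analysis.
    """
    return profile.L / (profile.L + profile.P)


def vickers_net_benefit(cohort: ScoredCohort, pt: float) -> float:
    """Classical decision-curve net benefit TP/n − FP/n · pt/(1−pt) at pt."""
    pt = float(pt)
    if not 0.0 < pt < 1.0:
        raise ValueError(f"threshold probability must lie in (0, 1), got {pt!r}")
    counts = confusion_at_threshold(cohort, pt)
    weight = pt / (1.0 - pt)
    return counts.tp / cohort.n - counts.fp / cohort.n * weight


@dataclasses.dataclass(frozen=True)
class ThresholdSelection:
    """A chosen decision threshold with its method and operating metrics.

    ``criterion_value`` holds the quantity the method optimized: J for
    Youden, the corner distance d for closest-to-corner, the floor target
    for fixed-sensitivity/-specificity, and NB0 at the crossing for the
    net-benefit intersection.
    """

    method: str
    threshold: float
    criterion_value: float
    metrics: DiagnosticMetrics
    counts: ConfusionCounts
    crossings: tuple = ()

    def predictions(self, cohort: ScoredCohort, *, strict: bool = False) -> np.ndarray:
        """Binary predictions of the selected threshold on a cohort."""
        if strict:
            return (cohort.scores > self.threshold).astype(np.int8)
        return (cohort.scores >= self.threshold).astype(np.int8)


def _selection(
    cohort: ScoredCohort, method: str, threshold: float, criterion: float, **kw
) -> ThresholdSelection:
    counts = confusion_at_threshold(cohort, threshold)
    return ThresholdSelection(
        method, float(threshold), float(criterion), metrics(counts), counts, **kw
    )


def _roc_candidates(cohort: ScoredCohort, roc: RocCurve | None):
    if roc is None:
        roc = roc_curve(cohort)
    # Exclude the sentinel: a selected threshold must be an attainable
    # cut-off inside [0, 1].
    return roc.candidate_thresholds(), roc.fpr[1:], roc.tpr[1:]


def _tie_break(thresholds, tpr, mask):
    """Among masked candidates: highest sensitivity, then smallest threshold.

    Screening prioritizes detection, hence the sensitivity-first rule; the
    final smallest-threshold rule makes the output deterministic.
    """
    idx = np.flatnonzero(mask)
    best_tpr = tpr[idx].max()
    idx = idx[tpr[idx] >= best_tpr - 1e-15]
    return idx[np.argmin(thresholds[idx])]


def youden_threshold(
    cohort: ScoredCohort, roc: RocCurve | None = None
) -> ThresholdSelection:
    """Maximize the Youden index J = Se + Sp − 1 over observed cut-offs."""
    thresholds, fpr, tpr = _roc_candidates(cohort, roc)
    j = tpr - fpr
    best = _tie_break(thresholds, tpr, j >= j.max() - 1e-12)
    return _selection(cohort, "youden", thresholds[best], j[best])


def closest_topleft_threshold(
    cohort: ScoredCohort, roc: RocCurve | None = None
) -> ThresholdSelection:
    """Minimize the distance from (FPR, TPR) to the perfect corner (0, 1)."""
    thresholds, fpr, tpr = _roc_candidates(cohort, roc)
    d = np.hypot(1.0 - tpr, fpr)
    best = _tie_break(thresholds, tpr, d <= d.min() + 1e-12)
    return _selection(cohort, "closest_topleft", thresholds[best], d[best])


def fixed_sensitivity_threshold(
    cohort: ScoredCohort, target_se: float, roc: RocCurve | None = None
) -> ThresholdSelection:
    """Largest threshold whose sensitivity is at least ``target_se``.

    Maximizes specificity subject to the sensitivity floor; with
    ``target_se=1.0`` this is the "miss nothing" screening setting, and
    the returned threshold equals the smallest positive score.
    """
    if not 0.0 < target_se <= 1.0:
        raise ValueError(f"target sensitivity must lie in (0, 1], got {target_se!r}")
    if cohort.n_pos == 0:
        raise ValueError("fixed-sensitivity selection needs at least one positive")
    thresholds, fpr, tpr = _roc_candidates(cohort, roc)
    mask = tpr >= target_se - 1e-12
    idx = np.flatnonzero(mask)
    best = idx[np.argmax(thresholds[idx])]
    return _selection(cohort, "fixed_sensitivity", thresholds[best], target_se)


def fixed_specificity_threshold(
    cohort: ScoredCohort, target_sp: float, roc: RocCurve | None = None
) -> ThresholdSelection:
    """Smallest threshold whose specificity is at least ``target_sp``."""
    if not 0.0 < target_sp <= 1.0:
        raise ValueError(f"target specificity must lie in (0, 1], got {target_sp!r}")
    if cohort.n_neg == 0:
        raise ValueError("fixed-specificity selection needs at least one negative")
    thresholds, fpr, tpr = _roc_candidates(cohort, roc)
    mask = (1.0 - fpr) >= target_sp - 1e-12
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        # Specificity 1 is always attainable just above the max score; use
        # the sentinel-equivalent cut-off 1.0 only if some score < 1 exists.
        raise ValueError(
            f"no observed cut-off reaches specificity {target_sp}"
        )
    best = idx[np.argmin(thresholds[idx])]
    return _selection(cohort, "fixed_specificity", thresholds[best], target_sp)


# ---------------------------------------------------------------------------
# Net-benefit curves and their intersection
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class NetBenefitCurves:
    """NB0(t) and NB1(t) evaluated on a strictly increasing grid in [0, 1).

    At t = 0 the boundary identities hold exactly: NB0(0) equals the
    prevalence and NB1(0) equals 1 − prevalence.  The grid excludes t = 1,
    where the weight t/(1 − t) diverges.
    """

    grid: np.ndarray
    nb0: np.ndarray
    nb1: np.ndarray
    n: int

    def difference(self) -> np.ndarray:
        return self.nb0 - self.nb1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.grid, "nb0": self.nb0, "nb1": self.nb1})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def default_nb_grid(cohort: ScoredCohort, n_points: int = 1001) -> np.ndarray:
    """Evenly spaced thresholds on [0, 1−ε] united with observed scores.

    The even grid keeps the curves smooth for interpolation; including the
    cohort's unique scores makes every count change exactly representable.
    """
    grid = np.linspace(0.0, 1.0 - GRID_EPS, n_points)
    observed = np.unique(cohort.scores)
    observed = observed[observed <= 1.0 - GRID_EPS]
    return np.union1d(grid, observed)


def _balanced_subcohort(cohort: ScoredCohort, rng: np.random.Generator) -> ScoredCohort:
    """Downsample the majority class to the minority count (no replacement)."""
    pos = np.flatnonzero(cohort.labels == 1)
    neg = np.flatnonzero(cohort.labels == 0)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("balancing requires both classes present")
    m = min(pos.size, neg.size)
    keep = np.concatenate(
        [rng.choice(pos, m, replace=False), rng.choice(neg, m, replace=False)]
    )
    keep.sort()
    return ScoredCohort(cohort.scores[keep], cohort.labels[keep])


def net_benefit_curves(
    cohort: ScoredCohort,
    grid: np.ndarray | None = None,
    *,
    p0: float | None = None,
    p1: float | None = None,
    balance: bool = False,
    rng: np.random.Generator | None = None,
) -> NetBenefitCurves:
    """Evaluate NB0 and NB1 over a threshold grid.

    Parameters
    ----------
    grid
        Strictly increasing thresholds in [0, 1−ε]; defaults to
        :func:`default_nb_grid`.
    p0, p1
        Optional fixed weight probabilities overriding the sweep value t in
        the NB0 (resp. NB1) weight, for use with externally supplied
        loss/profit ratios.
    balance
        If true, compute the curves on a class-balanced downsample of the
        cohort (majority class subsampled to the minority count, seeded by
        ``rng``).  Off by default.  Note that with exactly balanced classes
        and sweep weights the curve difference factors as
        J(t)·(1 − t/(1−t))/2, pinning any crossing to t = 0.5 wherever the
        classifier is informative.
    """
    if balance:
        cohort = _balanced_subcohort(
            cohort, rng if rng is not None else np.random.default_rng()
        )
    if grid is None:
        grid = default_nb_grid(cohort)
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 1:
        raise ValueError("grid must be a non-empty 1-D array")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    if grid[0] < 0 or grid[-1] > 1.0 - GRID_EPS + 1e-12:
        raise ValueError(
            f"grid must lie within [0, {1.0 - GRID_EPS}] "
            "(the weight t/(1-t) diverges at 1)"
        )
    for name, p in (("p0", p0), ("p1", p1)):
        if p is not None and not 0.0 <= p < 1.0:
            raise ValueError(f"{name} must lie in [0, 1), got {p!r}")
    tp, fp, tn, fn = sweep_counts(cohort, grid)
    n = cohort.n
    w0 = grid / (1.0 - grid) if p0 is None else p0 / (1.0 - p0)
    w1 = grid / (1.0 - grid) if p1 is None else p1 / (1.0 - p1)
    nb0 = tp / n - tn / n * w0
    nb1 = fp / n - fn / n * w1
    return NetBenefitCurves(grid, nb0, nb1, n)


def nb_intersection_threshold(
    cohort: ScoredCohort,
    curves: NetBenefitCurves | None = None,
    **curve_kwargs,
) -> ThresholdSelection:
    """Decision threshold at the NB0/NB1 intersection.

    Locates sign changes of D(t) = NB0(t) − NB1(t) on the grid and returns
    the linearly interpolated root inside the first (smallest-t)
    bracketing interval.  All crossings are recorded on the returned
    selection; more than one raises :class:`MultipleIntersectionsWarning`.
    Because the counts are step functions of t and the weight is smooth,
    linear interpolation between bracketing grid points is reproducible
    bit-for-bit; no iterative solver is involved.

    Raises
    ------
    NoIntersectionError
        If D has no sign change on the grid (advice: widen or densify the
        grid, or reconsider whether the cohort's prevalence admits a
        crossing at all; see the methods documentation).
    """
    if curves is None:
        curves = net_benefit_curves(cohort, **curve_kwargs)
    if curves.grid.size < 3:
        raise ValueError("need a grid of at least 3 points to bracket a crossing")
    grid, d = curves.grid, curves.difference()
    # A crossing is a transition between a strictly positive and a strictly
    # negative run of D.  Grid points where D is exactly zero form plateaus
    # (the curves coincide there, e.g. in uninformative tails) and are only
    # roots when flanked by runs of opposite sign.
    roots: list[float] = []
    sign = np.sign(d)
    nonzero = np.flatnonzero(sign != 0)
    for k in range(nonzero.size - 1):
        i, j = int(nonzero[k]), int(nonzero[k + 1])
        if sign[i] * sign[j] >= 0:
            continue
        if j == i + 1:
            t_lo, t_hi = grid[i], grid[j]
            roots.append(float(t_lo - d[i] * (t_hi - t_lo) / (d[j] - d[i])))
        else:
            # Zero run between the brackets: the curves touch; take its middle.
            roots.append(float(0.5 * (grid[i + 1] + grid[j - 1])))
    roots.sort()
    if not roots:
        raise NoIntersectionError(
            "NetBenefit0 and NetBenefit1 do not cross on the evaluated grid "
            f"[{grid[0]:g}, {grid[-1]:g}] ({grid.size} points); try a wider or "
            "denser grid. At low prevalence a crossing may not exist at all."
        )
    if len(roots) > 1:
        warnings.warn(
            f"multiple NB0/NB1 crossings at t = {np.round(roots, 6).tolist()}; "
            "using the smallest (most sensitivity-preserving in screening)",
            MultipleIntersectionsWarning,
        )
    t_star = roots[0]
    nb0_at = float(np.interp(t_star, grid, curves.nb0))
    return _selection(
        cohort, "nb_intersection", t_star, nb0_at, crossings=tuple(roots)
    )
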