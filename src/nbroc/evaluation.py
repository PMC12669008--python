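"""Paired evaluation of thresholding strategies.

Compares the predictions a cohort receives under different decision
thresholds (e.g. Youden vs. net-benefit intersection): confusion matrices
against ground truth, McNemar tests on the paired binary outcomes, and
cross-model aggregation of sensitivity/specificity/accuracy.

The McNemar test acts on the discordant counts (b, c) of a paired 2x2
table.  Following textbook practice the exact two-sided binomial test is
used when b + c < 25 and the continuity-corrected chi-square
(max(0, |b−c|−1))²/(b+c) with 1 df otherwise; both variants are callable
explicitly.  No multiple-testing correction is applied; reports state the
number of tests performed.
"""

from __future__ import annotations

import dataclasses
import json
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

from .cohort import ScoredCohort
from .roc import DiagnosticMetrics, metrics, roc_curve
from .thresholds import (
    ThresholdSelection,
    nb_intersection_threshold,
    youden_threshold,
)

__all__ = [
    "ComparisonReport",
    "McNemarResult",
    "PairedDichotomy",
    "compare_strategies",
    "mcnemar_test",
    "metrics_table_from_reports",
    "paired_table",
    "round_half_away_percent",
    "summarize_across_models",
    "validate_report_dict",
]

#: b + c below which the exact binomial variant is used by default.
EXACT_SWITCH = 25


@dataclasses.dataclass(frozen=True)
class PairedDichotomy:
    """2x2 cross-tabulation of two binary raters on the same subjects."""

    both_pos: int
    both_neg: int
    b: int  # reference positive, comparator negative
    c: int  # reference negative, comparator positive

    @property
    def n(self) -> int:
        return self.both_pos + self.both_neg + self.b + self.c

    @property
    def n_discordant(self) -> int:
        return self.b + self.c


@dataclasses.dataclass(frozen=True)
class McNemarResult:
    """McNemar test outcome; ``statistic`` is None for the exact variant."""

    statistic: float | None
    p_value: float
    method: str  # "exact_binomial" or "chi_square_cc"
    b: int
    c: int

    def display_p(self) -> str:
        """p to 4 significant figures with a '< 0.0001' floor."""
        if self.p_value < 1e-4:
            return "< 0.0001"
        return f"{self.p_value:.4g}"


def paired_table(pred_ref: Sequence[int], pred_alt: Sequence[int]) -> PairedDichotomy:
    """Cross-tabulate two binary prediction sequences of equal length."""
    ref = np.asarray(pred_ref)
    alt = np.asarray(pred_alt)
    if ref.shape != alt.shape or ref.ndim != 1:
        raise ValueError(
            f"paired sequences must be 1-D of equal length, got {ref.shape} vs {alt.shape}"
        )
    for name, arr in (("reference", ref), ("comparator", alt)):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} sequence contains non-binary values")
    both_pos = int(np.sum((ref == 1) & (alt == 1)))
    both_neg = int(np.sum((ref == 0) & (alt == 0)))
    b = int(np.sum((ref == 1) & (alt == 0)))
    c = int(np.sum((ref == 0) & (alt == 1)))
    return PairedDichotomy(both_pos, both_neg, b, c)


def mcnemar_test(table: PairedDichotomy, method: str = "auto") -> McNemarResult:
    """McNemar test on the discordant pair counts of a paired table.

    ``method`` is "auto" (exact when b + c < 25, else continuity-corrected
    chi-square), "exact", or "chi2".  b + c = 0 gives p = 1 by convention.
    """
    b, c = table.b, table.c
    if method not in ("auto", "exact", "chi2"):
        raise ValueError(f"unknown method {method!r}")
    if method == "auto":
        method = "exact" if b + c < EXACT_SWITCH else "chi2"
    if b + c == 0:
        stat = 0.0 if method == "chi2" else None
        return McNemarResult(stat, 1.0, _method_name(method), b, c)
    sm_table = [[table.both_pos, b], [c, table.both_neg]]
    if method == "exact":
        res = _sm_mcnemar(sm_table, exact=True)
        return McNemarResult(None, min(1.0, float(res.pvalue)), "exact_binomial", b, c)
    res = _sm_mcnemar(sm_table, exact=False, correction=True)
    # statsmodels' corrected statistic is (|b-c|-1)^2/(b+c), which goes
    # negative-side wrong only in the |b-c|<1 case; floor it at 0.
    stat = (max(0.0, abs(b - c) - 1.0)) ** 2 / (b + c)
    from scipy.stats import chi2

    p = float(chi2.sf(stat, df=1))
    return McNemarResult(stat, p, "chi_square_cc", b, c)


def _method_name(short: str) -> str:
    return {"exact": "exact_binomial", "chi2": "chi_square_cc"}[short]


# ---------------------------------------------------------------------------
# Strategy comparison reports
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class ComparisonReport:
    """Threshold selections, their metrics, and the paired McNemar tests.

    ``mcnemar_vs_truth`` compares each strategy's predictions against the
    ground-truth labels; ``mcnemar_between`` compares the second strategy's
    predictions against the first strategy's predictions taken as the
    reference (the Youden-as-reference convention when the default
    strategy pair is used).
    """

    n: int
    prevalence: float
    selections: dict[str, ThresholdSelection]
    mcnemar_vs_truth: dict[str, McNemarResult]
    mcnemar_between: McNemarResult | None
    n_tests: int

    def to_dict(self) -> dict:
        """JSON-ready dict; metrics rounded to 2 decimals for display."""
        out: dict = {
            "n": self.n,
            "prevalence": round(self.prevalence, 6),
            "n_mcnemar_tests": self.n_tests,
            "strategies": {},
            "mcnemar": {},
        }
        for name, sel in self.selections.items():
            m = sel.metrics.rounded(2)
            out["strategies"][name] = {
                "threshold": round(sel.threshold, 6),
                "criterion_value": round(sel.criterion_value, 6),
                "se": None if np.isnan(m.se) else m.se,
                "sp": None if np.isnan(m.sp) else m.sp,
                "acc": None if np.isnan(m.acc) else m.acc,
                "tp": sel.counts.tp,
                "fp": sel.counts.fp,
                "tn": sel.counts.tn,
                "fn": sel.counts.fn,
            }
        for name, res in self.mcnemar_vs_truth.items():
            out["mcnemar"][f"{name}_vs_truth"] = _mcnemar_dict(res)
        if self.mcnemar_between is not None:
            out["mcnemar"]["between_strategies"] = _mcnemar_dict(self.mcnemar_between)
        return out

    def to_json(self, path=None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, **kwargs)
        if path is not None:
            from pathlib import Path

            Path(path).write_text(text)
        return text

    def to_markdown(self) -> str:
        """Markdown table of per-strategy thresholds and metrics."""
        lines = [
            "| strategy | threshold | Se | Sp | Acc | McNemar vs truth |",
            "|---|---|---|---|---|---|",
        ]
        for name, sel in self.selections.items():
            m = sel.metrics.rounded(2)
            p = self.mcnemar_vs_truth[name].display_p()
            lines.append(
                f"| {name} | {sel.threshold:.4g} | {m.se:.2f} | {m.sp:.2f} "
                f"| {m.acc:.2f} | {p} |"
            )
        if self.mcnemar_between is not None:
            lines.append("")
            lines.append(
                "Between-strategy McNemar (first strategy as reference): "
                f"p {self.mcnemar_between.display_p()}"
            )
        return "\n".join(lines)


def _mcnemar_dict(res: McNemarResult) -> dict:
    return {
        "statistic": res.statistic,
        "p_value": res.p_value,
        "p_display": res.display_p(),
        "method": res.method,
        "b": res.b,
        "c": res.c,
    }


def compare_strategies(
    cohort: ScoredCohort,
    strategies: Sequence[str] = ("youden", "nb_intersection"),
    *,
    mcnemar_method: str = "auto",
    nb_kwargs: dict | None = None,
) -> ComparisonReport:
    """Select thresholds with each strategy and compare them pairwise.

    The default pair reproduces the screening comparison of interest:
    Youden-index threshold versus the net-benefit intersection threshold,
    each tested against ground truth and against one another (first
    strategy as reference).  Full precision is retained internally;
    rounding happens only in serialization.
    """
    if cohort.n_pos == 0 or cohort.n_neg == 0:
        raise ValueError("strategy comparison requires both classes present")
    roc = roc_curve(cohort)
    nb_kwargs = dict(nb_kwargs or {})
    selections: dict[str, ThresholdSelection] = {}
    for name in strategies:
        if name == "youden":
            selections[name] = youden_threshold(cohort, roc)
        elif name == "nb_intersection":
            try:
                selections[name] = nb_intersection_threshold(cohort, **nb_kwargs)
            except Exception as exc:
                raise type(exc)(f"strategy 'nb_intersection': {exc}") from exc
        else:
            raise ValueError(f"unknown strategy {name!r}")

    truth = cohort.labels
    vs_truth = {
        name: mcnemar_test(paired_table(truth, sel.predictions(cohort)), mcnemar_method)
        for name, sel in selections.items()
    }
    between = None
    if len(strategies) >= 2:
        ref = selections[strategies[0]].predictions(cohort)
        alt = selections[strategies[1]].predictions(cohort)
        between = mcnemar_test(paired_table(ref, alt), mcnemar_method)
    n_tests = len(vs_truth) + (1 if between is not None else 0)
    return ComparisonReport(
        cohort.n, cohort.prevalence, selections, vs_truth, between, n_tests
    )


# ---------------------------------------------------------------------------
# Cross-model aggregation
# ---------------------------------------------------------------------------


def round_half_away_percent(fraction: float) -> int:
    """Whole percent with round-half-away-from-zero (printed-table style)."""
    return int(
        Decimal(repr(float(fraction) * 100)).quantize(Decimal("1"), ROUND_HALF_UP)
    )


def metrics_table_from_reports(reports: Iterable[ComparisonReport]) -> pd.DataFrame:
    """Tidy (model, strategy, se, sp, acc) table from comparison reports."""
    rows = []
    for i, report in enumerate(reports):
        for strategy, sel in report.selections.items():
            rows.append(
                {
                    "model": i,
                    "strategy": strategy,
                    "se": sel.metrics.se,
                    "sp": sel.metrics.sp,
                    "acc": sel.metrics.acc,
                }
            )
    if not rows:
        raise ValueError("no reports supplied")
    return pd.DataFrame(rows)


def summarize_across_models(table: pd.DataFrame) -> pd.DataFrame:
    """Mean/min/max of Se, Sp, Acc per strategy across models.

    ``table`` is tidy with columns ``strategy``, ``se``, ``sp``, ``acc``
    (one row per model evaluation; see :func:`metrics_table_from_reports`).
    Returns one row per (strategy, metric) with the aggregate as a raw
    fraction and as a whole percent (round half away from zero, the
    convention of printed screening-accuracy tables).
    """
    required = {"strategy", "se", "sp", "acc"}
    if not isinstance(table, pd.DataFrame) or not required.issubset(table.columns):
        raise ValueError(f"need a DataFrame with columns {sorted(required)}")
    if len(table) == 0:
        raise ValueError("empty metric table")
    rows = []
    for strategy, group in table.groupby("strategy", sort=True):
        for metric in ("se", "sp", "acc"):
            values = group[metric].astype(float)
            agg = {
                "mean": float(values.mean()),
                "min": float(values.min()),
                "max": float(values.max()),
            }
            row = {"strategy": strategy, "metric": metric, "n_models": len(values)}
            for stat, value in agg.items():
                row[stat] = value
                row[f"{stat}_pct"] = round_half_away_percent(value)
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Report structure validation (schema shipped in nbroc/schemas/)
# ---------------------------------------------------------------------------

_STRATEGY_KEYS = {"threshold", "criterion_value", "se", "sp", "acc", "tp", "fp", "tn", "fn"}
_MCNEMAR_KEYS = {"statistic", "p_value", "p_display", "method", "b", "c"}


def validate_report_dict(data: dict) -> None:
    """Structural validation of a serialized comparison report.

    Raises ``ValueError`` naming the first offending field.  (Kept
    dependency-free; the JSON Schema document in ``nbroc/schemas``
    describes the same structure declaratively.)
    """
    for key in ("n", "prevalence", "n_mcnemar_tests", "strategies", "mcnemar"):
        if key not in data:
            raise ValueError(f"report missing key {key!r}")
    if not isinstance(data["strategies"], dict) or not data["strategies"]:
        raise ValueError("report 'strategies' must be a non-empty object")
    for name, entry in data["strategies"].items():
        missing = _STRATEGY_KEYS - set(entry)
        if missing:
            raise ValueError(f"strategy {name!r} missing fields {sorted(missing)}")
        if entry["threshold"] is None:
            raise ValueError(f"strategy {name!r} has no threshold")
    for name, entry in data["mcnemar"].items():
        missing = _MCNEMAR_KEYS - set(entry)
        if missing:
            raise ValueError(f"mcnemar {name!r} missing fields {sorted(missing)}")
        if not 0.0 <= entry["p_value"] <= 1.0:
            raise ValueError(f"mcnemar {name!r} p_value outside [0, 1]")
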