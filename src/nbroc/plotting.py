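"""ROC and net-benefit plots with selected thresholds marked."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)  # headless-safe default backend

import matplotlib.pyplot as plt

from .roc import RocCurve
from .thresholds import NetBenefitCurves, ThresholdSelection

__all__ = ["plot_roc", "plot_net_benefit"]

_MARKERS = {"youden": ("o", "tab:blue", "J"), "nb_intersection": ("s", "tab:red", "NB")}


def plot_roc(roc: RocCurve, selections=(), ax=None):
    """ROC curve with chance diagonal and selected operating points."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    ax.plot(roc.fpr, roc.tpr, color="black", lw=1.5, label=f"ROC (AUC {roc.auc:.3f})")
    ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
    for sel in selections:
        marker, color, tag = _MARKERS.get(sel.method, ("d", "tab:green", sel.method))
        fpr = 1.0 - sel.metrics.sp
        ax.plot(
            fpr,
            sel.metrics.se,
            marker,
            color=color,
            ms=8,
            label=f"{tag} (t={sel.threshold:.3g})",
        )
    ax.set_xlabel("False positive rate (1 − Sp)")
    ax.set_ylabel("True positive rate (Se)")
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    ax.legend(loc="lower right", fontsize=8)
    return ax


def plot_net_benefit(
    curves: NetBenefitCurves, selection: ThresholdSelection | None = None, ax=None
):
    """NB0 and NB1 against the threshold, vertical line at the crossing."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curves.grid, curves.nb0, label="NetBenefit0", color="tab:blue")
    ax.plot(curves.grid, curves.nb1, label="NetBenefit1", color="tab:orange")
    ax.axhline(0.0, color="grey", lw=0.6)
    if selection is not None:
        ax.axvline(
            selection.threshold,
            color="tab:red",
            ls="--",
            lw=1.0,
            label=f"t* = {selection.threshold:.4g}",
        )
    ax.set_xlabel("Decision threshold t")
    ax.set_ylabel("Net benefit")
    ax.legend(fontsize=8)
    return ax
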