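"""Figure helpers: metal-distribution violins, RCS curve, WQS weight bars."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_metal_violins", "plot_rcs_curve", "plot_wqs_weights"]

_UNITS = {"pb": "μmol/L", "cd": "nmol/L", "hg": "nmol/L"}


def plot_metal_violins(cohort: pd.DataFrame, out_path, metals=("pb", "cd", "hg")):
    """Violin plots of blood metal levels in cases vs controls."""
    fig, axes = plt.subplots(1, len(metals), figsize=(4 * len(metals), 4))
    axes = np.atleast_1d(axes)
    for ax, metal in zip(axes, metals):
        data = [
            cohort.loc[cohort["rvo_status"] == g, metal].dropna()
            for g in ("case", "control")
        ]
        ax.violinplot(data, showmedians=True)
        ax.set_xticks([1, 2], ["RVO", "Control"])
        ax.set_ylabel(f"Blood {metal.capitalize()} ({_UNITS.get(metal, '')})")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


def plot_rcs_curve(curve, out_path, metal: str = "pb"):
    """OR curve with CI band on a log-scaled exposure axis."""
    g = curve.grid
    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.plot(g["x"], g["or"], color="tab:blue")
    ax.fill_between(g["x"], g["ci_low"], g["ci_high"], alpha=0.2, color="tab:blue")
    ax.axhline(1.0, color="grey", lw=0.8, ls="--")
    ax.plot([10**curve.reference], [1.0], "ko", ms=5)
    ax.set_xscale("log")
    ax.set_xlabel(f"Blood {metal.capitalize()} ({_UNITS.get(metal, '')})")
    ax.set_ylabel("Odds ratio for RVO (ref: 25th percentile)")
    ax.set_title(f"Nonlinearity p = {curve.nonlinearity_p:.3f}")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


def plot_wqs_weights(result, out_path):
    """Signed per-metal weight bars from the WQS fit."""
    w = result.weights
    fig, ax = plt.subplots(figsize=(5, 4))
    colors = ["tab:red" if v >= 0 else "tab:blue" for v in w]
    ax.bar(w.index.str.capitalize(), w.values, color=colors)
    ax.axhline(0, color="black", lw=0.8)
    ax.set_ylabel("WQS weight (signed)")
    ax.set_title(
        f"score coef = {result.score_coefficient:.4f}, p = {result.score_p:.3f}"
    )
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
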