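"""Matplotlib figures for the benchmark reports.

Mirrors the three standard views: mean-sd relationships per scale, ROC
curves (with the operating point at the 5% estimated-FDR cutoff marked by
a cross), and TPR versus achieved FDR with filled points where the nominal
error rate is actually controlled.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

__all__ = ["plot_roc", "plot_tpr_fdr", "plot_mean_var", "plot_zero_profile"]


def plot_roc(curves: dict, ax=None, title="ROC"):
    """``curves`` maps method name -> RocCurve."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    for name, c in curves.items():
        ax.plot(c.fpr, c.tpr, label=f"{name} (AUC {c.auc:.3f})")
        if c.marker is not None:
            ax.plot(*c.marker, marker="x", ms=10, mew=2,
                    color=ax.lines[-1].get_color())
    ax.plot([0, 1], [0, 1], ls=":", color="gray", lw=0.8)
    ax.set(xlabel="FPR", ylabel="TPR", title=title, xlim=(0, 1), ylim=(0, 1.02))
    ax.legend(loc="lower right", fontsize=8)
    return ax


def plot_tpr_fdr(perfs: dict, ax=None, title="TPR vs achieved FDR"):
    """``perfs`` maps method name -> FdrPerformance."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    for name, p in perfs.items():
        if p.curve is not None:
            ax.plot(p.curve["achieved_fdr"], p.curve["tpr"], lw=1, label=name)
        color = ax.lines[-1].get_color() if ax.lines else None
        for _, row in p.table.iterrows():
            filled = bool(row["controlled"])
            ax.plot(row["achieved_fdr"], row["tpr"], marker="o", ms=7,
                    mfc=color if filled else "white", mec=color)
    ax.set(xlabel="achieved FDR", ylabel="TPR", title=title)
    ax.legend(loc="lower right", fontsize=8)
    return ax


def plot_mean_var(tables: dict, ax=None):
    """``tables`` maps scale name -> mean_var_table DataFrame."""
    n = len(tables)
    fig, axes = plt.subplots(1, n, figsize=(4 * n, 3.5), squeeze=False)
    for ax_i, (scale, tab) in zip(axes[0], tables.items()):
        ax_i.scatter(tab["mean"], tab["sd"], s=4, alpha=0.4)
        ax_i.set(xlabel="mean", ylabel="sd", title=scale)
    fig.tight_layout()
    return fig


def plot_zero_profile(profile, ax=None):
    """Bar plot of zero-in-one-condition frequency by expression bin."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    ax.bar(profile["bin"], profile["frac_zero_in_one"], width=0.9)
    ax.set(xlabel="expression bin (low to high)",
           ylabel="fraction all-zero in one condition")
    return ax
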