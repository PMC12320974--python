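"""Summary figures: group bar plots with s.e.m. and paired BTP/ATP line plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["bar_summary", "paired_lines"]

_LABELS = {"hr_bpm": "HR (BPM)", "ai_au": "AI (A.U.)", "fs_pct": "FS (%)"}


def bar_summary(metrics: pd.DataFrame, value: str, path: str | None = None):
    """Mean +/- s.e.m. bars per strain, split by BTP/ATP, dots for animals."""
    fig, ax = plt.subplots(figsize=(6, 4))
    strains = list(metrics["strain"].unique())
    width = 0.35
    rng = np.random.default_rng(0)  # jitter layout only
    for k, (cond, color) in enumerate((("BTP", "0.6"), ("ATP", "tab:red"))):
        sub = metrics[metrics["condition"] == cond]
        means = [sub.loc[sub["strain"] == s, value].mean() for s in strains]
        sems = [
            sub.loc[sub["strain"] == s, value].std(ddof=1)
            / np.sqrt(max((sub["strain"] == s).sum(), 1))
            for s in strains
        ]
        x = np.arange(len(strains)) + (k - 0.5) * width
        ax.bar(x, means, width, yerr=sems, capsize=3, color=color, label=cond)
        for i, s in enumerate(strains):
            vals = sub.loc[sub["strain"] == s, value]
            ax.plot(
                np.full(len(vals), x[i]) + rng.uniform(-0.08, 0.08, len(vals)),
                vals, ".", color="k", ms=3, alpha=0.5,
            )
    ax.set_xticks(np.arange(len(strains)), strains)
    ax.set_ylabel(_LABELS.get(value, value))
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def paired_lines(metrics: pd.DataFrame, value: str, path: str | None = None):
    """Per-animal BTP -> ATP lines, one panel per strain."""
    strains = list(metrics["strain"].unique())
    fig, axes = plt.subplots(1, len(strains), figsize=(2.2 * len(strains), 3.2), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, s in zip(axes, strains):
        sub = metrics[metrics["strain"] == s].pivot_table(
            index="animal_id", columns="condition", values=value, aggfunc="first"
        )
        for _, row in sub.iterrows():
            ax.plot([0, 1], [row.get("BTP"), row.get("ATP")], "-o", color="0.4", ms=3, lw=0.8)
        ax.set_xticks([0, 1], ["BTP", "ATP"])
        ax.set_title(s, fontsize=9)
    axes[0].set_ylabel(_LABELS.get(value, value))
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
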