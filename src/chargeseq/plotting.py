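"""Convenience figures: per-group fraction heatmap and condition barplot."""
from __future__ import annotations

from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns

from .quant import ChargingTable
from .stats import StatResult


def plot_heatmap(ct: ChargingTable, path) -> None:
    """Heatmap of charged fraction per group (rows) and sample (columns)."""
    n_rows = max(2, len(ct.group_ids))
    fig, ax = plt.subplots(figsize=(2 + 0.6 * len(ct.sample_ids), 1 + 0.3 * n_rows))
    sns.heatmap(
        ct.fractions * 100,
        vmin=0,
        vmax=100,
        cmap="viridis",
        annot=len(ct.group_ids) <= 30,
        fmt=".0f",
        cbar_kws={"label": "% charged"},
        ax=ax,
    )
    ax.set_xlabel("sample")
    ax.set_ylabel(ct.level)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_condition_bars(
    summary: pd.DataFrame, stats: Sequence[StatResult], path
) -> None:
    """Barplot of condition means +- SD with significance stars (q <= alpha)."""
    sig = {r.group_id for r in stats if r.significant}
    groups = list(dict.fromkeys(summary["group_id"]))
    conditions = list(dict.fromkeys(summary["condition"]))
    width = 0.8 / max(1, len(conditions))
    fig, ax = plt.subplots(figsize=(2 + 0.45 * len(groups) * len(conditions), 4))
    x = np.arange(len(groups))
    for ci, cond in enumerate(conditions):
        sub = summary[summary["condition"] == cond].set_index("group_id")
        means = sub.reindex(groups)["mean"] * 100
        sds = sub.reindex(groups)["sd"].fillna(0) * 100
        ax.bar(x + ci * width, means, width=width, yerr=sds, capsize=2, label=cond)
    for gi, group in enumerate(groups):
        if group in sig:
            top = (
                summary[summary["group_id"] == group]["mean"].max()
                + summary[summary["group_id"] == group]["sd"].fillna(0).max()
            ) * 100
            ax.text(gi + 0.4 * (len(conditions) - 1) * width, top + 2, "*",
                    ha="center", fontsize=14)
    ax.set_xticks(x + 0.4 * (len(conditions) - 1) * width)
    ax.set_xticklabels(groups, rotation=90)
    ax.set_ylabel("% charged (mean +- SD)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
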