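"""Figure-shaped outputs: recovery heatmap, rank bars, profiles, curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .loo import MATCH_RANKS

__all__ = [
    "plot_recovery_heatmap",
    "plot_rank_summary",
    "plot_baseline_profiles",
    "plot_iterative_curves",
]


def plot_recovery_heatmap(recovery: pd.DataFrame, path: str | Path) -> None:
    """Presence/absence heatmap of recovered genes, samples x genes."""
    fig, ax = plt.subplots(
        figsize=(0.35 * len(recovery.columns) + 2, 0.12 * len(recovery) + 2)
    )
    ax.imshow(recovery.to_numpy(dtype=float), aspect="auto", cmap="Greys", vmin=0, vmax=1)
    ax.set_xticks(range(len(recovery.columns)), recovery.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(recovery)), recovery.index, fontsize=4)
    ax.set_xlabel("gene region")
    ax.set_title("Gene recovery (dark = recovered)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_rank_summary(report, path: str | Path) -> None:
    """Stacked bars: % of samples assigned at each rank, per gene."""
    genes = list(report.summaries)
    bottom = np.zeros(len(genes))
    fig, ax = plt.subplots(figsize=(0.5 * len(genes) + 2, 4))
    for rank in MATCH_RANKS:
        vals = np.array([report.summaries[g].percentages[rank] for g in genes])
        ax.bar(genes, vals, bottom=bottom, label=rank)
        bottom += vals
    ax.set_ylabel("% of evaluated samples")
    ax.legend(fontsize=7, ncol=3)
    ax.set_title("Leave-one-out assignment rank by gene region")
    plt.setp(ax.get_xticklabels(), rotation=90, fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_baseline_profiles(profiles: pd.DataFrame, path: str | Path) -> None:
    """Heatmap of K2P distance from the baseline sample, samples x genes."""
    fig, ax = plt.subplots(
        figsize=(0.35 * len(profiles.columns) + 2, 0.12 * len(profiles) + 2)
    )
    im = ax.imshow(profiles.to_numpy(dtype=float), aspect="auto", cmap="viridis")
    fig.colorbar(im, ax=ax, label="K2P distance")
    ax.set_xticks(range(len(profiles.columns)), profiles.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(profiles)), profiles.index, fontsize=4)
    ax.set_title("K2P distance to baseline sample")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_iterative_curves(iterative: pd.DataFrame, path: str | Path) -> None:
    """Distance vs number of concatenated genes, one line per member."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    categories = list(dict.fromkeys(iterative["category"]))
    colors = plt.cm.tab10(np.linspace(0, 1, max(len(categories), 2)))
    cmap = dict(zip(categories, colors))
    for (member, cat), sub in iterative.groupby(["member", "category"], sort=False):
        ax.plot(sub["k"], sub["distance"], color=cmap[cat], alpha=0.7, lw=1)
    for cat in categories:
        ax.plot([], [], color=cmap[cat], label=cat)
    ax.set_xlabel("number of concatenated gene regions")
    ax.set_ylabel("K2P distance to baseline")
    ax.legend(fontsize=8)
    ax.set_title("Iterative gene concatenation")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
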