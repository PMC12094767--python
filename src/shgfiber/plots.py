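"""Simple figure exports: per-metric group boxplots and correlation heatmaps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["metric_boxplots", "correlation_heatmap"]


def metric_boxplots(
    table: pd.DataFrame,
    metrics: list[str],
    out_path: str | Path,
    group_col: str = "group",
) -> Path:
    """One boxplot panel per metric, split by group."""
    groups = sorted(table[group_col].unique())
    ncol = 4
    nrow = int(np.ceil(len(metrics) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 2.6 * nrow), squeeze=False)
    for ax, metric in zip(axes.ravel(), metrics):
        data = [table.loc[table[group_col] == g, metric].dropna() for g in groups]
        ax.boxplot(data, tick_labels=groups)
        ax.set_title(metric, fontsize=9)
    for ax in axes.ravel()[len(metrics):]:
        ax.axis("off")
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path


def correlation_heatmap(corr: pd.DataFrame, out_path: str | Path, title: str = "") -> Path:
    """Correlation matrix as a +/-1 diverging heatmap with value labels."""
    fig, ax = plt.subplots(figsize=(0.6 * len(corr) + 2, 0.6 * len(corr) + 1.5))
    im = ax.imshow(corr.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(corr)), corr.columns, rotation=90, fontsize=8)
    ax.set_yticks(range(len(corr)), corr.index, fontsize=8)
    for i in range(len(corr)):
        for j in range(len(corr)):
            v = corr.iloc[i, j]
            if np.isfinite(v):
                ax.text(j, i, f"{v:.2f}", ha="center", va="center", fontsize=6)
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
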