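"""Figures: log2 fold change vs m/z by lipid category, and a clustered
information-weighted correlation heatmap."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

CATEGORY_COLORS = {
    "FA": "#1b9e77",
    "GP": "#d95f02",
    "PK": "#7570b3",
    "PR": "#e7298a",
    "SP": "#66a61e",
}
_OTHER = "#999999"


def plot_fc_vs_mz(fold_changes: pd.DataFrame, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for cat, sub in fold_changes.groupby("category"):
        ax.scatter(
            sub.emf_mz,
            sub.log2_fc,
            s=18,
            alpha=0.8,
            label=cat,
            color=CATEGORY_COLORS.get(cat, _OTHER),
        )
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_xlabel("EMF m/z (minimum IMF m/z)")
    ax.set_ylabel("log2 fold change (case / control)")
    ax.legend(fontsize=8, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_correlation_heatmap(corr: pd.DataFrame, path: str | Path) -> None:
    vals = corr.fillna(0.0).values
    if vals.shape[0] > 2:
        d = 1.0 - vals
        np.fill_diagonal(d, 0.0)
        link = hierarchy.linkage(d[np.triu_indices_from(d, 1)], method="average")
        order = hierarchy.leaves_list(link)
        vals = vals[np.ix_(order, order)]
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(vals, cmap="RdBu_r", vmin=-1, vmax=1)
    fig.colorbar(im, ax=ax, label="weighted Pearson r")
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_title("EMF-EMF information-weighted correlation")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
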