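"""Minimal plotting: embedding scatter, proportion plots, silhouette heatmap.

All functions are pure renderers of the tables/arrays they receive — nothing
is recomputed — and return the matplotlib Figure (optionally saving it).
"""

from __future__ import annotations

from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .errors import ParameterError
from .quantify import ProportionTable

__all__ = ["plot_embedding", "plot_proportions", "plot_silhouette_heatmap"]


def _save(fig, path):
    if path is not None:
        fig.savefig(path, bbox_inches="tight", dpi=120)
    return fig


def plot_embedding(coords, labels=None, values=None, title: str = "", path=None):
    """2-D scatter colored by a categorical label or a continuous value
    (e.g. a gene's expression)."""
    coords = np.asarray(coords)
    fig, ax = plt.subplots(figsize=(5, 5))
    if values is not None:
        sc = ax.scatter(coords[:, 0], coords[:, 1], c=np.asarray(values), s=6, cmap="viridis")
        fig.colorbar(sc, ax=ax, shrink=0.8)
    else:
        lab = pd.Series(labels).astype(str)
        for k in sorted(lab.unique()):
            m = (lab == k).to_numpy()
            ax.scatter(coords[m, 0], coords[m, 1], s=6, label=k)
        ax.legend(markerscale=2, fontsize=7, loc="best")
    ax.set_title(title)
    ax.set_xticks([])
    ax.set_yticks([])
    return _save(fig, path)


def plot_proportions(tab: ProportionTable, path=None):
    """Pooled → stacked composition bars per group; unpooled → per-sample
    points grouped by condition with per-cluster test annotation."""
    if tab.mode == "pooled":
        wide = tab.data.pivot(index="group", columns="cluster", values="proportion")
        fig, ax = plt.subplots(figsize=(4, 4))
        bottom = np.zeros(len(wide))
        for k in wide.columns:
            ax.bar(wide.index, wide[k].to_numpy(), bottom=bottom, label=str(k))
            bottom += wide[k].to_numpy()
        ax.set_ylabel(f"proportion of {tab.reference}")
        ax.legend(fontsize=7)
        return _save(fig, path)
    if tab.mode != "unpooled":
        raise ParameterError(f"unknown proportion table mode {tab.mode!r}")
    clusters = sorted(tab.data["cluster"].astype(str).unique())
    groups = sorted(tab.data["group"].astype(str).unique())
    fig, ax = plt.subplots(figsize=(1.2 * len(clusters) + 1.5, 4))
    rng = np.random.default_rng(0)
    for ci, k in enumerate(clusters):
        for gi, g in enumerate(groups):
            sub = tab.data[
                (tab.data["cluster"].astype(str) == k) & (tab.data["group"].astype(str) == g)
            ]
            x = ci + (gi - (len(groups) - 1) / 2) * 0.3
            jitter = rng.uniform(-0.07, 0.07, len(sub))
            ax.plot(x + jitter, sub["proportion"], "o", ms=4, color=f"C{gi}",
                    label=g if ci == 0 else None)
    if tab.test is not None:
        top = tab.data["proportion"].max()
        for ci, k in enumerate(clusters):
            row = tab.test[tab.test["cluster"].astype(str) == k]
            if len(row):
                ax.annotate(
                    f"p={float(row['p_adj'].iloc[0]):.3g}",
                    (ci, top * 1.05),
                    ha="center",
                    fontsize=7,
                )
    ax.set_xticks(range(len(clusters)), clusters, rotation=45, ha="right")
    ax.set_ylabel(f"proportion of {tab.reference}")
    ax.legend(fontsize=8)
    return _save(fig, path)


def plot_silhouette_heatmap(comparison: pd.DataFrame, path=None):
    """Before/after per-cluster silhouette heatmap from
    :func:`screproject.evaluation.compare_embeddings` output."""
    rows = comparison[comparison["cluster"] != "__overall__"]
    mat = rows[["mean_width_before", "mean_width_after"]].to_numpy().T
    fig, ax = plt.subplots(figsize=(0.6 * len(rows) + 2, 2.4))
    im = ax.imshow(mat, vmin=-1, vmax=1, cmap="RdBu_r", aspect="auto")
    ax.set_yticks([0, 1], ["before", "after"])
    ax.set_xticks(range(len(rows)), rows["cluster"], rotation=45, ha="right", fontsize=7)
    for i in range(2):
        for j in range(len(rows)):
            ax.text(j, i, f"{mat[i, j]:.2f}", ha="center", va="center", fontsize=6)
    fig.colorbar(im, ax=ax, shrink=0.8, label="mean silhouette width")
    return _save(fig, path)
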