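"""Figure rendering: volcano plots, z-scored heatmaps, ORA dot plots,
distance heatmaps.

All functions take result tables, draw with matplotlib's non-interactive
backend, and save to file; they return the Figure so tests can inspect it.
Empty inputs produce a placeholder figure with a notice instead of failing.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .matrices import AbundanceMatrix
from .stats import DEFAULT_DE_CUTOFFS
from .structure import DistanceMatrix


def _placeholder(message: str, path):
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.text(0.5, 0.5, message, ha="center", va="center")
    ax.set_axis_off()
    fig.savefig(path)
    plt.close(fig)
    return fig


def volcano(de: pd.DataFrame, path, cutoffs=DEFAULT_DE_CUTOFFS, title: str = ""):
    """log2FC vs -log10 adjusted p, with the significance cutoffs drawn."""
    if not len(de):
        return _placeholder("no test results", path)
    fig, ax = plt.subplots(figsize=(5, 4))
    x = de["log2fc"]
    y = -np.log10(de["adj_p"].clip(lower=1e-300))
    sig = (de["adj_p"] <= cutoffs["max_adj_p"]) & (
        de["log2fc"].abs() >= cutoffs["min_abs_log2fc"]
    )
    ax.scatter(x[~sig], y[~sig], s=6, c="0.6", alpha=0.6, linewidths=0)
    ax.scatter(x[sig], y[sig], s=8, c="crimson", alpha=0.8, linewidths=0)
    ax.axhline(-np.log10(cutoffs["max_adj_p"]), ls="--", lw=0.8, c="k")
    for v in (-cutoffs["min_abs_log2fc"], cutoffs["min_abs_log2fc"]):
        ax.axvline(v, ls="--", lw=0.8, c="k")
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 adjusted p")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return fig


def zscore_rows(data: pd.DataFrame) -> pd.DataFrame:
    """Scale each feature row to mean 0, SD 1 (population SD, non-missing)."""
    mean = data.mean(axis=1, skipna=True)
    sd = data.std(axis=1, ddof=0, skipna=True).replace(0, np.nan)
    return data.sub(mean, axis=0).div(sd, axis=0)


def anova_heatmap(m: AbundanceMatrix, feature_ids, path, title: str = ""):
    """Heatmap of significant features, each row z-scored to mean 0 / SD 1."""
    rows = [f for f in feature_ids if f in m.data.index]
    if not rows:
        return _placeholder("no significant features", path)
    z = zscore_rows(m.data.loc[rows])
    fig, ax = plt.subplots(figsize=(6, max(2, 0.08 * len(rows) + 1)))
    im = ax.imshow(z.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-2.5, vmax=2.5)
    ax.set_xticks(range(len(z.columns)))
    ax.set_xticklabels(z.columns, rotation=90, fontsize=5)
    ax.set_yticks([])
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="row z-score")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return fig


def ora_dotplot(table: pd.DataFrame, path, max_sets: int = 20, title: str = ""):
    """Gene ratio vs set, point size = hit count, color = adjusted p."""
    if not len(table):
        return _placeholder("no over-represented sets", path)
    sub = table.nsmallest(max_sets, "adj_p").copy()
    sub["gene_ratio"] = sub["k"] / sub["n"].clip(lower=1)
    fig, ax = plt.subplots(figsize=(5, max(2, 0.3 * len(sub) + 1)))
    sc = ax.scatter(
        sub["gene_ratio"],
        range(len(sub)),
        s=20 + 10 * sub["k"],
        c=sub["adj_p"],
        cmap="viridis_r",
    )
    ax.set_yticks(range(len(sub)))
    ax.set_yticklabels(sub["set_id"], fontsize=7)
    ax.set_xlabel("gene ratio (k / n)")
    ax.set_title(title)
    fig.colorbar(sc, ax=ax, label="adjusted p")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return fig


def distance_heatmap(dm: DistanceMatrix, path, title: str = ""):
    """CA-CA distance heatmap with values annotated to one decimal; cells
    touching low-confidence sites are starred."""
    n = len(dm.labels)
    fig, ax = plt.subplots(figsize=(1 + 0.6 * n, 1 + 0.6 * n))
    im = ax.imshow(dm.distances.to_numpy(), cmap="magma_r")
    annotated = dm.annotate()
    for i, a in enumerate(dm.labels):
        for j, b in enumerate(dm.labels):
            ax.text(j, i, annotated.loc[a, b], ha="center", va="center", fontsize=7)
    ax.set_xticks(range(n))
    ax.set_xticklabels(dm.labels, rotation=90)
    ax.set_yticks(range(n))
    ax.set_yticklabels(dm.labels)
    ax.set_title(title or "CA-CA distances (A); * = low-confidence site")
    fig.colorbar(im, ax=ax, label="distance (A)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return fig
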