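"""Figure writers: clustered heatmap, PCA scatter, volcano."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .diffexp import OrdinationResult


def plot_heatmap(matrix: pd.DataFrame, ordination: OrdinationResult,
                 path: str | Path) -> None:
    ordered = matrix.loc[ordination.feature_order, ordination.sample_order]
    fig, ax = plt.subplots(figsize=(8, 6))
    im = ax.imshow(ordered.to_numpy(), aspect="auto", cmap="RdYlGn_r",
                   interpolation="nearest")
    ax.set_xticks(range(ordered.shape[1]))
    ax.set_xticklabels(ordered.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    ax.set_ylabel(f"{ordered.shape[0]} features")
    fig.colorbar(im, ax=ax, label="log2 expression")
    fig.tight_layout()
    fig.savefig(path, dpi=100, metadata={"Software": None})
    plt.close(fig)


def plot_pca(ordination: OrdinationResult, groups: pd.Series,
             path: str | Path) -> None:
    coords = ordination.pca_coords
    fig, ax = plt.subplots(figsize=(6, 5))
    for g in sorted(set(groups)):
        idx = [s for s in coords.index if groups.get(s) == g]
        ax.scatter(coords.loc[idx, "PC1"],
                   coords.loc[idx].iloc[:, 1] if coords.shape[1] > 1 else 0,
                   label=g, s=40)
    evr = ordination.explained_variance_ratio
    ax.set_xlabel(f"PC1 ({evr[0] * 100:.1f}%)")
    if len(evr) > 1:
        ax.set_ylabel(f"PC2 ({evr[1] * 100:.1f}%)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=100, metadata={"Software": None})
    plt.close(fig)


def plot_volcano(results: pd.DataFrame, path: str | Path,
                 alpha: float = 0.05, fc_threshold: float = 1.5,
                 use_adjusted: bool = True) -> None:
    p = results.p_adj if use_adjusted else results.p
    x = results.log2fc.to_numpy()
    y = -np.log10(p.to_numpy())
    hit = results["passes"].to_numpy() if "passes" in results else np.zeros(len(x), bool)
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(x[~hit], y[~hit], s=10, c="grey", alpha=0.6)
    ax.scatter(x[hit], y[hit], s=14, c="crimson")
    ax.axhline(-np.log10(alpha), ls="--", lw=0.8, c="k")
    for s in (np.log2(fc_threshold), -np.log2(fc_threshold)):
        ax.axvline(s, ls="--", lw=0.8, c="k")
    ax.set_xlabel("log2 fold-change")
    ax.set_ylabel("-log10 adjusted p" if use_adjusted else "-log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=100, metadata={"Software": None})
    plt.close(fig)
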