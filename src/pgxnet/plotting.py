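"""Matplotlib figures: ΔP heatmap, network map, variability overlay."""

from __future__ import annotations

import numpy as np

from .layout import ClusterAssignment, Layout2D
from .network import ItemNetwork
from .overlay import OverlayResult
from .posterior import PosteriorResult, order_heatmap


def _new_figure(figsize):
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt.subplots(figsize=figsize)


def plot_delta_heatmap(result: PosteriorResult, path=None, reorder: bool = True,
                       figsize=(8, 7)):
    """ΔP heatmap, blue positive / red negative, Ward-ordered by default."""
    fig, ax = _new_figure(figsize)
    order = order_heatmap(result) if reorder and len(result.genes) > 2 else np.arange(
        len(result.genes)
    )
    data = result.delta[np.ix_(order, order)]
    lim = float(np.abs(data).max()) or 1.0
    im = ax.imshow(data, cmap="RdBu", vmin=-lim, vmax=lim)
    labels = [result.genes[i] for i in order]
    if len(labels) <= 60:
        ax.set_xticks(range(len(labels)), labels, rotation=90, fontsize=5)
        ax.set_yticks(range(len(labels)), labels, fontsize=5)
    ax.set_xlabel("conditioning gene")
    ax.set_ylabel("responding gene")
    fig.colorbar(im, ax=ax, label="ΔP")
    if path:
        fig.savefig(path, bbox_inches="tight", dpi=150)
    return fig


def plot_network(layout: Layout2D, network: ItemNetwork,
                 clusters: ClusterAssignment | None = None, path=None, figsize=(8, 8)):
    """Item map; node size scales with the number of gene-drug interactions."""
    fig, ax = _new_figure(figsize)
    deg = np.concatenate([network.bipartite.sum(axis=1), network.bipartite.sum(axis=0)])
    size = 10 + 150 * deg / max(deg.max(), 1)
    color = clusters.labels if clusters is not None else (
        (layout.items["kind"] == "gene").astype(int)
    )
    genes = (layout.items["kind"] == "gene").to_numpy()
    ax.scatter(layout.coords[~genes, 0], layout.coords[~genes, 1], s=size[~genes],
               c=np.asarray(color)[~genes], cmap="tab10", marker="o", alpha=0.6,
               label="drugs")
    ax.scatter(layout.coords[genes, 0], layout.coords[genes, 1], s=size[genes],
               c=np.asarray(color)[genes], cmap="tab10", marker="s", alpha=0.9,
               edgecolors="k", linewidths=0.3, label="genes")
    ax.set_aspect("equal")
    ax.legend(loc="best", fontsize=8)
    ax.set_title(f"gene-drug interaction map ({network.mode})")
    if path:
        fig.savefig(path, bbox_inches="tight", dpi=150)
    return fig


def plot_overlay(layout: Layout2D, overlay: OverlayResult, path=None, figsize=(8, 8),
                 annotate_top: int = 8):
    """Gene map colored by hotspot score, sized by degree."""
    fig, ax = _new_figure(figsize)
    tab = overlay.table
    size = 10 + 150 * tab["degree"] / max(tab["degree"].max(), 1)
    sc = ax.scatter(tab["x"], tab["y"], c=tab["score"], s=size, cmap="viridis",
                    edgecolors="k", linewidths=0.3)
    for _, row in tab.head(annotate_top).iterrows():
        ax.annotate(row["gene"], (row["x"], row["y"]), fontsize=7,
                    xytext=(3, 3), textcoords="offset points")
    label = "MAF × degree" if overlay.weight_by_degree else "aggregated functional MAF"
    fig.colorbar(sc, ax=ax, label=label)
    ax.set_aspect("equal")
    ax.set_title("pharmacogenetic hotspot overlay")
    if path:
        fig.savefig(path, bbox_inches="tight", dpi=150)
    return fig
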