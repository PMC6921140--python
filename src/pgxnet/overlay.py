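"""Overlay of per-gene genetic variability onto the network layout.

Genes that sit close together on the map share metabolic patterns; genes
combining high functional variability with many drug links are the most
promising starting points when searching for combinatorial (gene-gene-drug)
pharmacogenetic effects.  Two scores are supported:

* ``maf_score`` alone — raw variability; and
* ``maf_score × degree`` — variability weighted by the number of drug
  interactions, treating pleiotropy as a measure of pharmacogenetic
  importance.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .io import VariabilityTable
from .layout import Layout2D
from .network import ItemNetwork

logger = logging.getLogger(__name__)


@dataclasses.dataclass(eq=False)
class OverlayResult:
    """Per-gene coordinates, degree, variability and hotspot ranking.

    ``table`` columns: gene, x, y, degree, maf_score, score, rank; sorted by
    rank (1 = strongest hotspot candidate).
    """

    table: pd.DataFrame
    weight_by_degree: bool

    @property
    def n_genes(self) -> int:
        return len(self.table)


def overlay_variability(
    layout: Layout2D,
    network: ItemNetwork,
    variability: VariabilityTable,
    weight_by_degree: bool = False,
) -> OverlayResult:
    """Annotate gene nodes with variability and rank hotspot candidates.

    Genes missing from the variability table score 0 (with a warning) so
    the layout stays complete; ties in the score are broken by gene id.
    """
    gene_mask = (layout.items["kind"] == "gene").to_numpy()
    genes = layout.items.loc[gene_mask, "id"].tolist()
    if genes != network.gene_ids:
        raise ValueError("layout and network gene sets differ")
    coords = layout.coords[gene_mask]
    degrees = network.bipartite.sum(axis=1).astype(np.int64)

    matched = [g for g in genes if g in variability]
    if len(variability) and not matched:
        raise ValueError("variability table and layout share no genes")
    missing = [g for g in genes if g not in variability]
    if missing:
        logger.warning("%d gene(s) missing from variability table score 0: %s",
                       len(missing), missing[:10])
    unmatched = [g for g in variability.scores.index if g not in set(genes)]
    if unmatched:
        logger.warning("%d variability gene(s) not in the layout: %s",
                       len(unmatched), unmatched[:10])

    maf = np.array([variability.get(g) for g in genes])
    score = maf * degrees if weight_by_degree else maf.copy()
    df = pd.DataFrame(
        {
            "gene": genes,
            "x": coords[:, 0],
            "y": coords[:, 1],
            "degree": degrees,
            "maf_score": maf,
            "score": score,
        }
    )
    df = df.sort_values(["score", "gene"], ascending=[False, True], kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    return OverlayResult(table=df.reset_index(drop=True), weight_by_degree=weight_by_degree)


def hotspot_report(overlay: OverlayResult, top_k: int, n_neighbors: int = 3) -> pd.DataFrame:
    """Top-k hotspot genes with their nearest neighbors on the map.

    The neighbors (by Euclidean layout distance, nearest first) are the
    candidate epistasis partners: spatial proximity encodes shared
    metabolic patterns.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    n = overlay.n_genes
    if top_k > n:
        logger.warning("top_k=%d exceeds %d genes; truncating", top_k, n)
        top_k = n
    df = overlay.table
    coords = df[["x", "y"]].to_numpy()
    genes = df["gene"].to_numpy()
    dist = cdist(coords, coords)
    np.fill_diagonal(dist, np.inf)
    rows = []
    for idx in range(top_k):
        order = np.argsort(dist[idx], kind="stable")[: min(n_neighbors, n - 1)]
        rows.append(
            {
                "rank": int(df["rank"].iloc[idx]),
                "gene": genes[idx],
                "x": df["x"].iloc[idx],
                "y": df["y"].iloc[idx],
                "degree": int(df["degree"].iloc[idx]),
                "maf_score": df["maf_score"].iloc[idx],
                "importance": df["score"].iloc[idx],
                "nearest_neighbors": ",".join(genes[order]),
            }
        )
    return pd.DataFrame(rows)
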