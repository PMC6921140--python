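"""Unified gene+drug item network with association-strength similarity.

Every gene and every drug is a node.  Each node carries an occurrence total
w_i (its weighted bipartite degree in the gene-drug table) and each node
pair a co-occurrence count c_ij.  Similarity is the association strength

    s_ij = c_ij / (w_i * w_j),

which normalizes shared occurrences by how common the two items are, so a
rare gene sharing its few drugs with another rare gene scores higher than
two ubiquitous hubs sharing many.

Co-occurrence is defined on one unified matrix:

* gene-drug: the link weight itself (number of pharmacogenomic labels,
  minimum 1, in ``weighted`` mode; 1 in ``unweighted`` mode);
* gene-gene: over shared drugs, the sum of the smaller of the two link
  weights (plain shared-drug count when all weights are 1);
* drug-drug: symmetrically over shared genes.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .io import AssociationMatrix

MODES = ("weighted", "unweighted")


class DegenerateNetworkError(ValueError):
    """A network statistic is undefined for this graph (e.g. constant degrees)."""


@dataclasses.dataclass(eq=False)
class ItemNetwork:
    """Unified node set (genes then drugs) with co-occurrence and similarity.

    ``items`` is a DataFrame with columns ``id``, ``kind`` ('gene'/'drug')
    and ``occurrence`` (w_i), in the same order as the rows of
    ``cooccurrence`` and ``similarity``.  ``bipartite`` keeps the binary
    gene x drug incidence and ``weights`` the edge weights actually used,
    for degree computations and assortativity.
    """

    items: pd.DataFrame
    cooccurrence: np.ndarray
    similarity: np.ndarray
    mode: str
    bipartite: np.ndarray
    weights: np.ndarray

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def n_genes(self) -> int:
        return int((self.items["kind"] == "gene").sum())

    @property
    def n_drugs(self) -> int:
        return int((self.items["kind"] == "drug").sum())

    @property
    def gene_ids(self) -> list:
        return self.items.loc[self.items["kind"] == "gene", "id"].tolist()

    @property
    def drug_ids(self) -> list:
        return self.items.loc[self.items["kind"] == "drug", "id"].tolist()


def _pairwise_min_overlap(W: np.ndarray, chunk: int = 64) -> np.ndarray:
    """C[a, b] = sum_k min(W[a, k], W[b, k]) computed in row chunks."""
    n = W.shape[0]
    out = np.empty((n, n))
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        out[start:stop] = np.minimum(W[start:stop, None, :], W[None, :, :]).sum(axis=2)
    return out


def build_network(matrix: AssociationMatrix, mode: str = "weighted") -> ItemNetwork:
    """Build the unified item network from an association matrix.

    In ``weighted`` mode gene-drug links carry their pharmacogenomic label
    count (links without labels weigh 1); ``unweighted`` treats every link
    as weight 1.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    inc = matrix.incidence.astype(np.int64)
    if mode == "weighted":
        W = np.maximum(matrix.label_counts, 1) * inc
    else:
        W = inc.copy()
    W = W.astype(np.float64)

    n_g, n_d = W.shape
    n = n_g + n_d
    c = np.zeros((n, n))
    c[:n_g, n_g:] = W
    c[n_g:, :n_g] = W.T
    c[:n_g, :n_g] = _pairwise_min_overlap(W)
    c[n_g:, n_g:] = _pairwise_min_overlap(W.T)
    np.fill_diagonal(c, 0.0)

    w = np.concatenate([W.sum(axis=1), W.sum(axis=0)])
    s = c / np.outer(w, w)

    items = pd.DataFrame(
        {
            "id": list(matrix.genes) + list(matrix.drugs),
            "kind": ["gene"] * n_g + ["drug"] * n_d,
            "occurrence": w,
        }
    )
    return ItemNetwork(
        items=items,
        cooccurrence=c,
        similarity=s,
        mode=mode,
        bipartite=matrix.incidence.astype(np.int8),
        weights=W,
    )


def _pearson_edge_degrees(deg_a: np.ndarray, deg_b: np.ndarray) -> float:
    """Pearson correlation of end degrees over an edge list (both orientations)."""
    x = np.concatenate([deg_a, deg_b]).astype(np.float64)
    y = np.concatenate([deg_b, deg_a]).astype(np.float64)
    vx = x.var()
    vy = y.var()
    if vx == 0 or vy == 0:
        raise DegenerateNetworkError(
            "degree assortativity undefined: zero degree variance at edge ends"
        )
    return float(((x - x.mean()) * (y - y.mean())).mean() / np.sqrt(vx * vy))


def assortativity(network: ItemNetwork, graph: str = "items", weighted: bool = False) -> float:
    """Degree assortativity: Pearson correlation of edge-end degrees.

    Each undirected edge contributes both orientations.  ``graph`` selects
    the edge set:

    * ``'items'`` (default) — the unified item graph over genes and drugs,
      with an edge wherever co-occurrence c_ij > 0.  Drugs sharing a
      pleiotropic gene form large mutually-connected groups here, so
      heavy-tailed real-scale tables come out assortative, matching the
      behaviour of the visualized network.
    * ``'bipartite'`` — raw gene-drug links only.  At realistic margins
      (one gene linked to most drugs next to many one-drug genes) this
      edge set is intrinsically disassortative, whatever the planted
      structure.

    With ``weighted=True`` node strengths (summed edge weights) replace
    plain degrees.  Zero degree variance raises
    :class:`DegenerateNetworkError` rather than returning NaN.
    """
    if graph == "items":
        adj = network.cooccurrence > 0
        a, b = np.nonzero(np.triu(adj, k=1))
        if len(a) < 2:
            raise DegenerateNetworkError("assortativity needs at least 2 edges")
        deg = network.cooccurrence.sum(axis=1) if weighted else adj.sum(axis=1)
        return _pearson_edge_degrees(deg[a], deg[b])
    if graph == "bipartite":
        gi, dj = np.nonzero(network.bipartite)
        if len(gi) < 2:
            raise DegenerateNetworkError("assortativity needs at least 2 edges")
        if weighted:
            deg_g = network.weights.sum(axis=1)
            deg_d = network.weights.sum(axis=0)
        else:
            deg_g = network.bipartite.sum(axis=1)
            deg_d = network.bipartite.sum(axis=0)
        return _pearson_edge_degrees(deg_g[gi], deg_d[dj])
    raise ValueError("graph must be 'items' or 'bipartite'")


def edge_list_assortativity(edges) -> float:
    """Degree assortativity of an arbitrary undirected simple graph.

    ``edges`` is an iterable of 2-tuples of hashable node ids, each
    undirected edge listed once.  Provided for generic graphs; the pipeline
    itself uses :func:`assortativity` on the bipartite edge set.
    """
    edges = list(edges)
    if len(edges) < 2:
        raise DegenerateNetworkError("assortativity needs at least 2 edges")
    deg: dict = {}
    for a, b in edges:
        deg[a] = deg.get(a, 0) + 1
        deg[b] = deg.get(b, 0) + 1
    da = np.array([deg[a] for a, _ in edges], dtype=float)
    db = np.array([deg[b] for _, b in edges], dtype=float)
    return _pearson_edge_degrees(da, db)


def degree_report(network: ItemNetwork) -> pd.DataFrame:
    """Per-item link count and strength, sorted by descending degree then id."""
    deg = np.concatenate([network.bipartite.sum(axis=1), network.bipartite.sum(axis=0)])
    strength = np.concatenate([network.weights.sum(axis=1), network.weights.sum(axis=0)])
    df = pd.DataFrame(
        {
            "id": network.items["id"],
            "kind": network.items["kind"],
            "degree": deg.astype(np.int64),
            "strength": strength,
        }
    )
    return df.sort_values(["degree", "id"], ascending=[False, True], kind="mergesort").reset_index(
        drop=True
    )


def write_edgelist(network: ItemNetwork, path, sep: str = "\t") -> None:
    """Write item pairs with positive co-occurrence as a flat table."""
    a, b = np.nonzero(np.triu(network.cooccurrence > 0, k=1))
    ids = network.items["id"].to_numpy()
    kinds = network.items["kind"].to_numpy()
    df = pd.DataFrame(
        {
            "item1": ids[a],
            "item2": ids[b],
            "kind1": kinds[a],
            "kind2": kinds[b],
            "c": network.cooccurrence[a, b],
            "s": network.similarity[a, b],
        }
    ).sort_values(["item1", "item2"], kind="mergesort")
    df.to_csv(Path(path), sep=sep, index=False, float_format="%.10g")


def to_networkx(network: ItemNetwork):
    """Export as a networkx Graph (similarity-weighted edges) for viewers."""
    import networkx as nx

    g = nx.Graph(mode=network.mode)
    for _, row in network.items.iterrows():
        g.add_node(row["id"], kind=row["kind"], occurrence=float(row["occurrence"]))
    ids = network.items["id"].to_numpy()
    a, b = np.nonzero(np.triu(network.cooccurrence > 0, k=1))
    for i, j in zip(a, b):
        g.add_edge(
            ids[i],
            ids[j],
            c=float(network.cooccurrence[i, j]),
            s=float(network.similarity[i, j]),
        )
    return g


def write_graphml(network: ItemNetwork, path) -> None:
    import networkx as nx

    nx.write_graphml(to_networkx(network), Path(path))
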