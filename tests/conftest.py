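"""Shared fixtures and independent oracles for the test suite.

The oracles deliberately avoid the package's vectorized code paths: ΔP is
recomputed from explicit per-drug Python sets, co-occurrence by pairwise
enumeration, assortativity by a hand-rolled Pearson over edge-end degrees,
and the constrained layout objective by a generic numeric minimizer.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.spatial.distance import pdist, squareform

from pgxnet import AssociationMatrix, ItemNetwork


# ----------------------------------------------------------------------
# matrix builders


def random_association_matrix(rng, n_genes, n_drugs, p=0.4):
    """Random binary matrix with isolated rows/columns repaired."""
    inc = (rng.random((n_genes, n_drugs)) < p).astype(int)
    for i in np.nonzero(inc.sum(axis=1) == 0)[0]:
        inc[i, rng.integers(n_drugs)] = 1
    for j in np.nonzero(inc.sum(axis=0) == 0)[0]:
        inc[rng.integers(n_genes), j] = 1
    genes = [f"G{i:02d}" for i in range(n_genes)]
    drugs = [f"D{j:02d}" for j in range(n_drugs)]
    labels = inc * rng.integers(0, 4, size=inc.shape)
    return AssociationMatrix(genes, drugs, inc, labels)


def worked_example_matrix():
    """212 drugs; gene A linked to 141, gene B to 94, 81 shared.

    A filler gene linked to every drug keeps all drugs non-isolated without
    changing any pairwise quantity between A and B.
    """
    n_drugs = 212
    drugs = [f"D{j:03d}" for j in range(n_drugs)]
    inc = np.zeros((3, n_drugs), dtype=int)
    inc[0, :141] = 1                      # CYP3A4-like hub
    inc[1, :81] = 1                       # ABCB1-like: 81 shared ...
    inc[1, 141:154] = 1                   # ... plus 13 exclusive = 94 total
    inc[2, :] = 1                         # filler covers every drug
    return AssociationMatrix(["CYP3A4", "ABCB1", "ZFILLER"], drugs, inc)


def similarity_network(s):
    """Wrap a bare similarity matrix as an ItemNetwork for layout tests."""
    s = np.asarray(s, dtype=float)
    n = len(s)
    items = pd.DataFrame(
        {"id": [f"N{i}" for i in range(n)], "kind": ["gene"] * n, "occurrence": 1.0}
    )
    return ItemNetwork(
        items=items,
        cooccurrence=s.copy(),
        similarity=s.copy(),
        mode="unweighted",
        bipartite=np.ones((n, 1), dtype=np.int8),
        weights=np.ones((n, 1)),
    )


# ----------------------------------------------------------------------
# oracles


def brute_delta_p(matrix):
    """ΔP by explicit set intersections, one pair at a time."""
    drug_sets = [
        {matrix.drugs[j] for j in range(matrix.n_drugs) if matrix.incidence[i, j]}
        for i in range(matrix.n_genes)
    ]
    n = matrix.n_genes
    delta = np.empty((n, n))
    for i in range(n):
        p_i = len(drug_sets[i]) / matrix.n_drugs
        for j in range(n):
            cond = len(drug_sets[i] & drug_sets[j]) / len(drug_sets[j])
            delta[i, j] = cond - p_i
    return delta


def brute_cooccurrence(weights):
    """Unified co-occurrence by enumeration: min-weight overlap within type,
    the edge weight itself across types."""
    n_g, n_d = weights.shape
    n = n_g + n_d
    c = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            if a == b:
                continue
            if a < n_g and b < n_g:
                c[a, b] = sum(min(weights[a, k], weights[b, k]) for k in range(n_d))
            elif a >= n_g and b >= n_g:
                c[a, b] = sum(min(weights[k, a - n_g], weights[k, b - n_g]) for k in range(n_g))
            elif a < n_g:
                c[a, b] = weights[a, b - n_g]
            else:
                c[a, b] = weights[b, a - n_g]
    return c


def brute_assortativity(edges):
    """Pearson over edge-end degrees, both orientations, from first principles."""
    deg = {}
    for a, b in edges:
        deg[a] = deg.get(a, 0) + 1
        deg[b] = deg.get(b, 0) + 1
    xs, ys = [], []
    for a, b in edges:
        xs += [deg[a], deg[b]]
        ys += [deg[b], deg[a]]
    x, y = np.array(xs, float), np.array(ys, float)
    return float(((x - x.mean()) * (y - y.mean())).mean() / (x.std() * y.std()))


def oracle_layout_objective(s, restarts=100, seed=0):
    """Best objective of the constrained layout found by a generic minimizer.

    Minimizes V(X / C(X)) unconstrained (the constraint is scale-only) with
    BFGS from many random starts.
    """
    s = np.asarray(s, dtype=float)
    n = len(s)
    s_c = squareform(s, checks=False)
    m = n * (n - 1) / 2

    def f(x):
        coords = x.reshape(n, 2)
        d = pdist(coords)
        c = d.sum() / m
        if c == 0:
            return 1e9
        return float((s_c * (d / c) ** 2).sum())

    rng = np.random.default_rng(seed)
    best = np.inf
    for _ in range(restarts):
        res = minimize(f, rng.uniform(-0.5, 0.5, 2 * n), method="BFGS")
        best = min(best, res.fun)
    return best


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
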