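"""Constrained 2D embedding of the item network by iterative majorization.

The map places every item (gene or drug) at coordinates x_i ∈ R² by
minimizing the association-strength weighted squared-distance objective

    V(x_1, …, x_n) = Σ_{i<j} s_ij ‖x_i − x_j‖²

subject to the scale constraint

    (2 / (n(n−1))) Σ_{i<j} ‖x_i − x_j‖ = 1,

i.e. the mean pairwise Euclidean distance is fixed at 1, which prevents the
trivial solution of collapsing all points into one coordinate.  Similar
items are pulled together while the constraint keeps the cloud spread out.

Algorithm
---------
Because V is homogeneous of degree 2 and the constraint of degree 1 in the
coordinates, the constrained problem is equivalent (up to overall scale) to
unconstrained minimization of

    G(X) = V(X) − Σ_{i<j} ‖x_i − x_j‖,

whose stationarity condition reproduces the Lagrange condition of the
constrained problem.  G is minimized by iterative majorization in the
SMACOF family: the concave −Σ‖x_i−x_j‖ term is bounded above by its tangent
at the current configuration Z, giving a quadratic surrogate whose minimum
solves the linear system 2 L_s X = B(Z) Z, with L_s the Laplacian of the
similarity matrix and B(Z) the Laplacian of the all-pairs 1/d_ij(Z)
weights.  After each update the configuration is rescaled to the
closed-form scale optimum of G; at that scale G = −m²/(4·V̂) with
m = n(n−1)/2 and V̂ the objective of the constraint-normalized
configuration, so monotone descent of G implies monotone descent of the
reported objective.  Returned coordinates are normalized to constraint
value exactly 1, centered at the origin, principal-axis aligned, and
reflection-fixed, so runs are comparable.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy.cluster import hierarchy
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .network import ItemNetwork

logger = logging.getLogger(__name__)


class DegenerateLayoutError(ValueError):
    """The similarity matrix admits no meaningful layout (e.g. all zeros)."""


@dataclasses.dataclass(eq=False)
class Layout2D:
    """A converged 2D embedding of the item network.

    ``coords[i]`` is the position of ``items.iloc[i]``; ``objective`` is the
    final V = Σ s_ij‖x_i−x_j‖² and ``constraint_value`` the mean pairwise
    distance (1 at convergence).  ``objective_history`` records V of the
    constraint-normalized iterate at every majorization step.
    """

    items: pd.DataFrame
    coords: np.ndarray
    objective: float
    constraint_value: float
    converged: bool
    iterations: int
    seed: int
    objective_history: np.ndarray

    @property
    def n_items(self) -> int:
        return len(self.items)

    def subset(self, mask) -> "Layout2D":
        """Restrict to a boolean mask of items (coordinates unchanged).

        The constraint value is recomputed for the subset and will generally
        differ from 1; subsets are meant for downstream clustering and
        reporting, not as converged layouts.
        """
        mask = np.asarray(mask, dtype=bool)
        coords = self.coords[mask]
        return Layout2D(
            items=self.items.loc[mask].reset_index(drop=True),
            coords=coords,
            objective=float("nan"),
            constraint_value=_mean_pairwise_distance(coords),
            converged=self.converged,
            iterations=self.iterations,
            seed=self.seed,
            objective_history=self.objective_history,
        )


@dataclasses.dataclass(eq=False)
class ClusterAssignment:
    """Cluster labels for the items of a layout."""

    items: pd.DataFrame
    labels: np.ndarray
    method: str
    k: int
    quality: float  # inertia for k-means, cophenetic cut height for Ward


def _mean_pairwise_distance(coords: np.ndarray) -> float:
    n = len(coords)
    if n < 2:
        return 0.0
    return float(pdist(coords).sum() / (n * (n - 1) / 2))


def constraint_value(layout: Layout2D) -> float:
    """Mean pairwise Euclidean distance (2/(n(n−1)))·Σ_{i<j}‖x_i−x_j‖."""
    return _mean_pairwise_distance(layout.coords)


def layout_objective(similarity: np.ndarray, coords: np.ndarray) -> float:
    """V = Σ_{i<j} s_ij ‖x_i − x_j‖² for given coordinates."""
    s_cond = squareform(np.asarray(similarity, dtype=float), checks=False)
    return float((s_cond * pdist(coords) ** 2).sum())


def _canonicalize(coords: np.ndarray) -> np.ndarray:
    """Fix the rigid-motion gauge: center, principal-axis align, fix signs."""
    x = coords - coords.mean(axis=0)
    # rotate principal axis of the point cloud onto the first coordinate
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    x = x @ vt.T
    for axis in range(x.shape[1]):
        col = x[:, axis]
        nz = np.nonzero(np.abs(col) > 1e-9)[0]
        if len(nz) and col[nz[0]] < 0:
            x[:, axis] = -col
    return x


def _fit_single(s: np.ndarray, x0: np.ndarray, max_iter: int, tol: float, solve):
    """One majorization run; returns (coords at constraint 1, history, converged)."""
    n = len(s)
    m = n * (n - 1) / 2.0
    s_cond = squareform(s, checks=False)
    X = x0 - x0.mean(axis=0)
    history = []
    prev_v = np.inf
    converged = False
    for _ in range(max_iter):
        d = pdist(X)
        with np.errstate(divide="ignore"):
            inv_d = np.where(d > 0, 1.0 / np.maximum(d, 1e-300), 0.0)
        Bw = squareform(inv_d)
        BZ = Bw.sum(axis=1)[:, None] * X - Bw @ X  # (diag(row sums) − Bw) @ X
        X = 0.5 * solve(BZ)
        X -= X.mean(axis=0)
        d_new = pdist(X)
        c = d_new.sum() / m
        if c == 0:
            raise DegenerateLayoutError("layout collapsed to a single point")
        Y = X / c
        v = float((s_cond * (d_new / c) ** 2).sum())
        history.append(v)
        if prev_v - v <= tol * max(v, 1e-300):
            converged = True
            X = Y
            break
        prev_v = v
        X = Y * (m / (2.0 * v))  # closed-form scale optimum of G
    else:
        X = X / (_mean_pairwise_distance(X) or 1.0)
    return X, np.array(history), converged


def layout_vos(
    network: ItemNetwork,
    seed: int = 42,
    max_iter: int = 1000,
    tol: float = 1e-8,
    n_starts: int = 5,
) -> Layout2D:
    """Fit the constrained association-strength layout of an item network.

    Parameters
    ----------
    network : ItemNetwork
        Provides the symmetric nonnegative similarity matrix and item table.
    seed : int
        Seeds the uniform [−0.5, 0.5]² initial configurations; identical
        seeds give bit-identical coordinates.
    max_iter, tol : int, float
        Majorization stops when the relative objective decrease falls below
        ``tol`` or after ``max_iter`` iterations.
    n_starts : int
        Independent random restarts; the run with the lowest final
        objective is kept.
    """
    s = np.asarray(network.similarity, dtype=np.float64)
    n = len(s)
    if n < 2:
        raise ValueError("layout needs at least 2 items")
    if not np.allclose(s, s.T):
        raise ValueError("similarity matrix must be symmetric")
    if (s < 0).any():
        raise ValueError("similarity matrix must be nonnegative")
    if not (s > 0).any():
        raise DegenerateLayoutError("all-zero similarity matrix")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")

    s = (s + s.T) / 2.0
    np.fill_diagonal(s, 0.0)
    L = np.diag(s.sum(axis=1)) - s
    n_comp, _ = connected_components(s > 0, directed=False)
    if n_comp == 1:
        factor = sla.cho_factor(L + np.ones((n, n)) / n)

        def solve(rhs):
            out = sla.cho_solve(factor, rhs)
            return out - out.mean(axis=0)

    else:
        logger.warning(
            "similarity graph has %d disconnected components; "
            "between-component placement is underdetermined",
            n_comp,
        )

        def solve(rhs):
            out = np.linalg.lstsq(L, rhs, rcond=None)[0]
            return out - out.mean(axis=0)

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_starts):
        x0 = rng.uniform(-0.5, 0.5, size=(n, 2))
        coords, history, conv = _fit_single(s, x0, max_iter, tol, solve)
        v = history[-1] if len(history) else np.inf
        if best is None or v < best[0]:
            best = (v, coords, history, conv)

    _, coords, history, conv = best
    coords = _canonicalize(coords)
    coords = coords / _mean_pairwise_distance(coords)  # exact renormalization
    return Layout2D(
        items=network.items.copy(),
        coords=coords,
        objective=layout_objective(s, coords),
        constraint_value=_mean_pairwise_distance(coords),
        converged=conv,
        iterations=len(history),
        seed=seed,
        objective_history=history,
    )


# ----------------------------------------------------------------------
# clustering of the embedded configuration


def cluster_kmeans(layout: Layout2D, k: int, seed: int = 0) -> ClusterAssignment:
    """K-means on the 2D coordinates (Lloyd, max 300 iterations, tol 1e-4).

    Ten random initializations are run and the best-inertia solution kept;
    deterministic for a fixed seed.  Labels are renumbered by order of first
    appearance so equivalent partitions compare equal.
    """
    from sklearn.cluster import KMeans

    _check_k(k, layout.n_items)
    km = KMeans(n_clusters=k, n_init=10, max_iter=300, tol=1e-4, random_state=seed)
    labels = km.fit_predict(layout.coords)
    labels = _relabel_first_appearance(labels)
    return ClusterAssignment(
        items=layout.items, labels=labels, method="kmeans", k=k, quality=float(km.inertia_)
    )


def cluster_agglomerative(layout: Layout2D, k: int) -> ClusterAssignment:
    """Ward-linkage agglomerative clustering on Euclidean distances, cut at k.

    Fully deterministic: scipy's Ward implementation breaks merge ties by
    the smallest pair of cluster indices.
    """
    _check_k(k, layout.n_items)
    n = layout.n_items
    if k == n:
        labels = np.arange(n)
        height = 0.0
    else:
        link = hierarchy.linkage(layout.coords, method="ward")
        labels = hierarchy.fcluster(link, t=k, criterion="maxclust") - 1
        height = float(link[-(k - 1), 2]) if k > 1 else float(link[-1, 2])
        labels = _relabel_first_appearance(labels)
    return ClusterAssignment(
        items=layout.items, labels=labels, method="agglomerative", k=k, quality=height
    )


def choose_k(layout: Layout2D, k_max: int | None = None, seed: int = 0) -> int:
    """Silhouette-optimal cluster count over k in [2, min(15, n−1)]."""
    from sklearn.cluster import KMeans
    from sklearn.metrics import silhouette_score

    n = layout.n_items
    if n < 3:
        return min(2, n)
    upper = min(15 if k_max is None else k_max, n - 1)
    best_k, best_score = 2, -np.inf
    for k in range(2, upper + 1):
        labels = KMeans(n_clusters=k, n_init=10, max_iter=300, tol=1e-4, random_state=seed).fit_predict(
            layout.coords
        )
        score = silhouette_score(layout.coords, labels)
        if score > best_score + 1e-12:
            best_k, best_score = k, score
    return best_k


def _check_k(k: int, n: int) -> None:
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")


def _relabel_first_appearance(labels: np.ndarray) -> np.ndarray:
    mapping: dict = {}
    out = np.empty(len(labels), dtype=np.int64)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def write_layout(layout: Layout2D, path, clusters: ClusterAssignment | None = None, degrees=None,
                 sep: str = "\t") -> None:
    """Write an item/coordinate table (plus optional degree and cluster columns)."""
    df = pd.DataFrame(
        {
            "item": layout.items["id"],
            "kind": layout.items["kind"],
            "x": layout.coords[:, 0],
            "y": layout.coords[:, 1],
        }
    )
    if degrees is not None:
        df["degree"] = np.asarray(degrees, dtype=np.int64)
    if clusters is not None:
        df["cluster"] = clusters.labels
    df.to_csv(path, sep=sep, index=False, float_format="%.10g")
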