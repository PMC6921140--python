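"""Constrained 2D layout: constraint arithmetic, monotone descent, oracles,
and clustering of the embedded configuration."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from pgxnet import (
    DegenerateLayoutError,
    Layout2D,
    build_network,
    choose_k,
    cluster_agglomerative,
    cluster_kmeans,
    constraint_value,
    generate,
    layout_vos,
    SyntheticConfig,
)
from conftest import oracle_layout_objective, similarity_network


def _layout_from_coords(coords):
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    items = pd.DataFrame({"id": [f"N{i}" for i in range(n)], "kind": ["gene"] * n,
                          "occurrence": 1.0})
    return Layout2D(items=items, coords=coords, objective=0.0,
                    constraint_value=float(pdist(coords).mean()) if n > 1 else 0.0,
                    converged=True, iterations=0, seed=0,
                    objective_history=np.array([]))


class TestConstraint:
    def test_two_points_at_distance_one(self):
        lay = layout_vos(similarity_network([[0, 2.0], [2.0, 0]]), seed=0)
        assert np.linalg.norm(lay.coords[0] - lay.coords[1]) == pytest.approx(1.0, abs=1e-9)

    def test_equal_similarities_give_equilateral_triangle(self):
        s = np.full((3, 3), 0.7)
        np.fill_diagonal(s, 0)
        lay = layout_vos(similarity_network(s), seed=0, tol=1e-13, max_iter=5000)
        np.testing.assert_allclose(pdist(lay.coords), 1.0, atol=1e-6)

    def test_constraint_value_is_mean_pairwise_distance(self):
        lay = _layout_from_coords([[0, 0], [1, 0], [0, 1]])
        expected = (1 + 1 + np.sqrt(2)) / 3
        assert constraint_value(lay) == pytest.approx(expected)

    def test_constraint_linear_in_scale(self):
        lay = _layout_from_coords([[0, 0], [1, 0]])
        doubled = _layout_from_coords(2 * lay.coords)
        assert constraint_value(doubled) == pytest.approx(2 * constraint_value(lay))

    def test_converged_layout_satisfies_constraint(self):
        m, _, _ = generate(SyntheticConfig(n_genes=10, n_drugs=40, seed=2))
        lay = layout_vos(build_network(m, "weighted"), seed=2)
        assert lay.converged
        assert constraint_value(lay) == pytest.approx(1.0, abs=1e-6)


class TestDescentAndDeterminism:
    def test_objective_monotone_nonincreasing(self):
        m, _, _ = generate(SyntheticConfig(n_genes=12, n_drugs=50, seed=4))
        lay = layout_vos(build_network(m, "weighted"), seed=4, n_starts=1)
        h = lay.objective_history
        assert len(h) > 1
        assert np.all(np.diff(h) <= 1e-9 * np.maximum(h[:-1], 1.0))

    def test_identical_seed_bit_identical_coordinates(self):
        m, _, _ = generate(SyntheticConfig(n_genes=8, n_drugs=30, seed=6))
        net = build_network(m, "weighted")
        a = layout_vos(net, seed=123)
        b = layout_vos(net, seed=123)
        assert np.array_equal(a.coords, b.coords)

    def test_canonical_gauge_centered_and_axis_aligned(self):
        m, _, _ = generate(SyntheticConfig(n_genes=8, n_drugs=30, seed=6))
        lay = layout_vos(build_network(m, "weighted"), seed=1)
        np.testing.assert_allclose(lay.coords.mean(axis=0), 0.0, atol=1e-9)
        cov = lay.coords.T @ lay.coords
        assert abs(cov[0, 1]) < 1e-6  # principal axes aligned
        assert cov[0, 0] >= cov[1, 1]


class TestErrors:
    def test_all_zero_similarity_raises(self):
        with pytest.raises(DegenerateLayoutError):
            layout_vos(similarity_network(np.zeros((3, 3))), seed=0)

    def test_single_item_raises(self):
        with pytest.raises(ValueError):
            layout_vos(similarity_network(np.zeros((1, 1))), seed=0)


class TestOracleAgreement:
    @pytest.mark.parametrize("n,seed", [(4, 0), (5, 1), (6, 2)])
    def test_objective_matches_independent_minimizer(self, n, seed):
        rng = np.random.default_rng(seed)
        s = rng.random((n, n))
        s = (s + s.T) / 2
        np.fill_diagonal(s, 0)
        ours = layout_vos(similarity_network(s), seed=0, n_starts=20, tol=1e-12,
                          max_iter=3000).objective
        oracle = oracle_layout_objective(s, restarts=80, seed=seed)
        assert ours == pytest.approx(oracle, abs=1e-4)


class TestSimilarityDistanceConcordance:
    def test_within_block_closer_than_between(self):
        cfg = SyntheticConfig(n_genes=20, n_drugs=80, n_blocks=2, p_in=0.6,
                              p_out=0.02, seed=0)
        matrix, _, truth = generate(cfg)
        lay = layout_vos(build_network(matrix, "weighted"), seed=0, n_starts=2)
        gene_coords = lay.coords[(lay.items["kind"] == "gene").to_numpy()]
        dm = squareform(pdist(gene_coords))
        same = truth.gene_blocks[:, None] == truth.gene_blocks[None, :]
        iu = np.triu_indices(len(gene_coords), 1)
        assert dm[iu][same[iu]].mean() < dm[iu][~same[iu]].mean()


class TestClustering:
    def _blobs(self):
        return _layout_from_coords(
            [[0, 0], [0.1, 0], [0, 0.1], [5, 5], [5.1, 5], [5, 5.1]]
        )

    def test_kmeans_recovers_separated_blobs(self):
        assign = cluster_kmeans(self._blobs(), 2, seed=0)
        labels = assign.labels
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_kmeans_k_equals_n_gives_zero_inertia(self):
        assign = cluster_kmeans(self._blobs(), 6, seed=0)
        assert len(set(assign.labels)) == 6
        assert assign.quality == pytest.approx(0.0, abs=1e-12)

    def test_kmeans_k_one_inertia_is_total_scatter(self):
        lay = self._blobs()
        assign = cluster_kmeans(lay, 1, seed=0)
        centered = lay.coords - lay.coords.mean(axis=0)
        assert assign.quality == pytest.approx((centered ** 2).sum())

    def test_k_out_of_range_raises(self):
        with pytest.raises(ValueError):
            cluster_kmeans(self._blobs(), 7, seed=0)
        with pytest.raises(ValueError):
            cluster_agglomerative(self._blobs(), 0)

    def test_agglomerative_recovers_separated_blobs(self):
        assign = cluster_agglomerative(self._blobs(), 2)
        labels = assign.labels
        assert len(set(labels[:3])) == 1 and labels[0] != labels[3]

    def test_agglomerative_collinear_points_pair_adjacent(self):
        lay = _layout_from_coords([[0, 0], [1, 0], [2, 0], [3, 0]])
        labels = cluster_agglomerative(lay, 2).labels
        assert labels[0] == labels[1] and labels[2] == labels[3]
        assert labels[0] != labels[2]

    def test_agglomerative_singletons_at_k_equals_n(self):
        assert len(set(cluster_agglomerative(self._blobs(), 6).labels)) == 6

    def test_choose_k_finds_two_blobs(self):
        assert choose_k(self._blobs()) == 2


class TestModeRobustness:
    def test_weighted_and_unweighted_layouts_concordant(self):
        """The map topology barely changes when label weights are dropped
        (the robustness the analysis relies on)."""
        from scipy.spatial import procrustes

        m, _, _ = generate(SyntheticConfig(seed=3))
        lw = layout_vos(build_network(m, "weighted"), seed=0, n_starts=3)
        lu = layout_vos(build_network(m, "unweighted"), seed=0, n_starts=3)
        _, _, disparity = procrustes(lw.coords, lu.coords)
        assert disparity < 0.1
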