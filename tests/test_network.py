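"""Item network: association strength, degrees, assortativity."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pgxnet import (
    AssociationMatrix,
    DegenerateNetworkError,
    assortativity,
    build_network,
    degree_report,
    edge_list_assortativity,
    generate,
    paper_scale_preset,
)
from conftest import (
    brute_assortativity,
    brute_cooccurrence,
    random_association_matrix,
    worked_example_matrix,
)


class TestBuildNetwork:
    def test_minimal_single_link(self):
        m = AssociationMatrix(["G1"], ["D1"], np.array([[1]]))
        net = build_network(m, mode="unweighted")
        np.testing.assert_allclose(net.items["occurrence"], [1.0, 1.0])
        assert net.similarity[0, 1] == pytest.approx(1.0)
        assert net.cooccurrence[0, 0] == 0.0

    def test_unweighted_equals_weighted_with_unit_labels(self, rng):
        m = random_association_matrix(rng, 6, 10)
        unit = AssociationMatrix(m.genes, m.drugs, m.incidence, m.incidence.astype(int))
        np.testing.assert_allclose(
            build_network(m, "unweighted").similarity,
            build_network(unit, "weighted").similarity,
        )

    def test_similarity_matches_enumeration_oracle(self):
        rng = np.random.default_rng(9)
        m = random_association_matrix(rng, 3, 4)
        net = build_network(m, mode="weighted")
        W = np.maximum(m.label_counts, 1) * m.incidence
        c = brute_cooccurrence(W)
        w = np.concatenate([W.sum(axis=1), W.sum(axis=0)]).astype(float)
        np.testing.assert_allclose(net.cooccurrence, c)
        np.testing.assert_allclose(net.similarity, c / np.outer(w, w))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_similarity_symmetric_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        m = random_association_matrix(rng, int(rng.integers(2, 7)), int(rng.integers(2, 9)))
        net = build_network(m, mode="weighted")
        np.testing.assert_allclose(net.similarity, net.similarity.T)
        assert (net.similarity >= 0).all() and (net.cooccurrence >= 0).all()

    def test_scaling_edge_weights_scales_cooccurrence(self, rng):
        m = random_association_matrix(rng, 5, 8)
        lab = np.maximum(m.label_counts, 1) * m.incidence
        scaled = AssociationMatrix(m.genes, m.drugs, m.incidence, 3 * lab)
        base = AssociationMatrix(m.genes, m.drugs, m.incidence, lab)
        net_b, net_s = build_network(base, "weighted"), build_network(scaled, "weighted")
        np.testing.assert_allclose(net_s.cooccurrence, 3 * net_b.cooccurrence)
        # degree assortativity is scale-free in both variants
        assert assortativity(net_s) == pytest.approx(assortativity(net_b))
        assert assortativity(net_s, weighted=True) == pytest.approx(
            assortativity(net_b, weighted=True)
        )


class TestAssortativity:
    def test_triangle_plus_edge_is_perfectly_assortative(self):
        edges = [(0, 1), (1, 2), (2, 0), (3, 4)]
        assert edge_list_assortativity(edges) == pytest.approx(1.0)

    def test_path_of_four_nodes(self):
        # endpoint degrees (1,2),(2,2),(2,1) → Pearson −0.5 by hand
        assert edge_list_assortativity([(0, 1), (1, 2), (2, 3)]) == pytest.approx(-0.5)

    def test_cycle_constant_degree_raises(self):
        with pytest.raises(DegenerateNetworkError):
            edge_list_assortativity([(0, 1), (1, 2), (2, 3), (3, 0)])

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_pearson_and_networkx(self, seed):
        """Random bipartite graphs up to 12 nodes, three-way agreement."""
        rng = np.random.default_rng(seed)
        m = random_association_matrix(rng, int(rng.integers(2, 7)), int(rng.integers(2, 7)))
        gi, dj = np.nonzero(m.incidence)
        edges = [(f"g{i}", f"d{j}") for i, j in zip(gi, dj)]
        g = nx.Graph(edges)
        try:
            expected = brute_assortativity(edges)
        except ZeroDivisionError:
            return
        net = build_network(m, "unweighted")
        got = assortativity(net, graph="bipartite")
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(nx.degree_assortativity_coefficient(g), abs=1e-9)

    def test_item_graph_matches_networkx(self, rng):
        m = random_association_matrix(rng, 5, 7)
        net = build_network(m, "unweighted")
        g = nx.from_numpy_array((net.cooccurrence > 0).astype(int))
        assert assortativity(net, graph="items") == pytest.approx(
            nx.degree_assortativity_coefficient(g), abs=1e-9
        )

    def test_paper_scale_preset_is_assortative(self):
        """Heavy-tailed realistic tables give a positive assortativity index."""
        for seed in (0, 1):
            m, _, _ = generate(paper_scale_preset(seed=seed))
            assert assortativity(build_network(m, "weighted")) > 0

    def test_hub_with_private_specialists_is_disassortative(self):
        """One hub gene plus per-drug specialist genes: low-degree specialists
        attach to high-degree items only."""
        k = 12
        genes = ["HUB"] + [f"S{i:02d}" for i in range(k)]
        inc = np.vstack([np.ones(k, dtype=int), np.eye(k, dtype=int)])
        m = AssociationMatrix(genes, [f"D{i:02d}" for i in range(k)], inc)
        assert assortativity(build_network(m, "unweighted")) < 0


class TestDegreeReport:
    def test_minimal_network(self):
        m = AssociationMatrix(["G1"], ["D1"], np.array([[1]]))
        rep = degree_report(build_network(m, "unweighted"))
        assert rep["degree"].tolist() == [1, 1]

    def test_hub_degree_matches_link_count(self):
        rep = degree_report(build_network(worked_example_matrix(), "unweighted"))
        assert int(rep.loc[rep["id"] == "CYP3A4", "degree"].iloc[0]) == 141

    def test_recount_oracle(self, rng):
        m = random_association_matrix(rng, 6, 9)
        rep = degree_report(build_network(m, "weighted")).set_index("id")
        for i, g in enumerate(m.genes):
            assert rep.loc[g, "degree"] == m.incidence[i].sum()
        for j, d in enumerate(m.drugs):
            assert rep.loc[d, "degree"] == m.incidence[:, j].sum()

    def test_sorted_by_degree_then_id(self, rng):
        rep = degree_report(build_network(random_association_matrix(rng, 6, 9), "weighted"))
        keys = list(zip(-rep["degree"], rep["id"]))
        assert keys == sorted(keys)
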