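"""Markov Clustering: matrix steps, attractor extraction, partition contracts."""

import itertools

import networkx as nx
import numpy as np
import pytest

from goclust import mcl_core
from goclust.mcl_core import (
    ClusterPartition, TransitionMatrix, build_matrix, expand, extract_clusters,
    inflate, mcl,
)
import oracles


def graph_from_edges(n_nodes, weighted_edges):
    G = nx.Graph()
    G.add_nodes_from(f"n{i}" for i in range(n_nodes))
    for u, v, w in weighted_edges:
        G.add_edge(f"n{u}", f"n{v}", weight=w)
    return G


class TestBuildMatrix:
    def test_isolated_node(self):
        tm = build_matrix(graph_from_edges(1, []), self_loop=1.0)
        assert tm.matrix.shape == (1, 1)
        assert tm.matrix[0, 0] == 1.0

    def test_two_nodes_one_edge(self):
        tm = build_matrix(graph_from_edges(2, [(0, 1, 1.0)]), self_loop=1.0)
        assert np.allclose(tm.matrix, 0.5)

    def test_columns_stochastic(self):
        tm = build_matrix(graph_from_edges(3, [(0, 1, 1.0), (1, 2, 1.0)]))
        assert np.allclose(tm.matrix.sum(axis=0), 1.0, atol=1e-9)
        assert (tm.matrix >= 0).all()

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            build_matrix(nx.Graph())


class TestExpand:
    def test_identity_fixed_point(self):
        I = np.eye(4)
        assert np.array_equal(expand(I), I)

    def test_projection_fixed_point(self):
        M = np.full((2, 2), 0.5)
        assert np.allclose(expand(M), M)

    def test_matches_naive_triple_loop(self):
        rng = np.random.default_rng(3)
        M = rng.random((4, 4))
        M /= M.sum(axis=0, keepdims=True)
        naive = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                for k in range(4):
                    naive[i, j] += M[i, k] * M[k, j]
        assert np.allclose(expand(M), naive, atol=1e-12)


class TestInflate:
    def test_deterministic_column_unchanged(self):
        M = np.array([[1.0, 0.0], [0.0, 1.0]])
        for r in (1.5, 2.0, 5.0):
            assert np.allclose(inflate(M, r), M)

    def test_symmetric_column_invariant(self):
        M = np.array([[0.5], [0.5]])
        assert np.allclose(inflate(M, 2.0), M)

    def test_hand_computed_example(self):
        M = np.array([[0.8], [0.2]])
        out = inflate(M, 2.0)
        assert out[0, 0] == pytest.approx(0.64 / 0.68)
        assert out[1, 0] == pytest.approx(0.04 / 0.68)

    def test_pruning_floor_zeroes_tiny_entries(self):
        M = np.array([[1.0 - 1e-9], [1e-9]])
        out = inflate(M, 2.0, prune=1e-5)
        assert out[1, 0] == 0.0
        assert out[0, 0] == 1.0

    @pytest.mark.parametrize("r", [1.0, 0.5, -2.0])
    def test_inflation_must_exceed_one(self, r):
        with pytest.raises(ValueError):
            inflate(np.eye(2), r)


class TestExtract:
    def test_identity_gives_singletons(self):
        tm = TransitionMatrix(np.eye(3), ("a", "b", "c"))
        part = extract_clusters(tm)
        assert part.clusters == (frozenset({"a"}), frozenset({"b"}),
                                 frozenset({"c"}))

    def test_block_mass_gives_block_clusters(self):
        M = np.zeros((4, 4))
        M[0, 0] = M[0, 1] = 1.0  # attractor a captures a, b
        M[2, 2] = M[2, 3] = 1.0  # attractor c captures c, d
        part = extract_clusters(TransitionMatrix(M, ("a", "b", "c", "d")))
        assert set(part.clusters) == {frozenset({"a", "b"}),
                                      frozenset({"c", "d"})}

    def test_weakly_shared_node_goes_to_larger_entry(self):
        M = np.zeros((4, 4))
        M[0, 0] = 1.0
        M[1, 1] = 1.0
        M[0, 2], M[1, 2] = 0.4, 0.6  # node 2 claimed by both attractors
        M[1, 3] = 1.0
        part = extract_clusters(TransitionMatrix(M, ("a", "b", "c", "d")))
        assert set(part.clusters) == {frozenset({"a"}),
                                      frozenset({"b", "c", "d"})}


class TestMcl:
    def test_disconnected_cliques_never_merge(self):
        edges = [(i, j, 1.0) for i, j in itertools.combinations(range(3), 2)]
        edges += [(i, j, 1.0) for i, j in itertools.combinations(range(3, 6), 2)]
        part = mcl(graph_from_edges(6, edges), inflation=1.5)
        assert set(part.clusters) == {frozenset({"n0", "n1", "n2"}),
                                      frozenset({"n3", "n4", "n5"})}

    def test_single_node(self):
        part = mcl(graph_from_edges(1, []))
        assert part.clusters == (frozenset({"n0"}),)

    def test_barbell_splits_at_weak_bridge(self):
        edges = [(i, j, 1.0) for i, j in itertools.combinations(range(3), 2)]
        edges += [(i, j, 1.0) for i, j in itertools.combinations(range(3, 6), 2)]
        edges.append((2, 3, 0.1))
        part = mcl(graph_from_edges(6, edges), inflation=2.0)
        assert set(part.clusters) == {frozenset({"n0", "n1", "n2"}),
                                      frozenset({"n3", "n4", "n5"})}
        # and it agrees with the independent naive iteration
        oracle = oracles.mcl_reference([f"n{i}" for i in range(6)],
                                       [(f"n{u}", f"n{v}", w) for u, v, w in edges],
                                       inflation=2.0)
        assert sorted(part.clusters, key=lambda c: (-len(c), min(c))) == oracle

    def test_inflation_must_exceed_one(self):
        with pytest.raises(ValueError):
            mcl(graph_from_edges(2, [(0, 1, 1.0)]), inflation=1.0)

    def test_determinism(self):
        rng = np.random.default_rng(11)
        G = nx.gnp_random_graph(12, 0.3, seed=4)
        H = nx.relabel_nodes(G, {i: f"n{i}" for i in G})
        for u, v in H.edges:
            H[u][v]["weight"] = float(rng.choice([0.5, 1.0]))
        assert mcl(H, inflation=1.6).clusters == mcl(H, inflation=1.6).clusters

    @pytest.mark.parametrize("seed", range(5))
    def test_partition_and_component_refinement(self, seed):
        rng = np.random.default_rng(seed)
        G = nx.gnp_random_graph(15, 0.2, seed=seed)
        H = nx.relabel_nodes(G, {i: f"n{i:02d}" for i in G})
        for u, v in H.edges:
            H[u][v]["weight"] = float(rng.choice([0.5, 1.0]))
        part = mcl(H, inflation=1.5)
        # strict partition over all nodes
        assert part.nodes == frozenset(H.nodes)
        assert sum(len(c) for c in part.clusters) == len(H)
        # every cluster inside one connected component
        comp_of = {}
        for i, comp in enumerate(nx.connected_components(H)):
            for node in comp:
                comp_of[node] = i
        for cluster in part.clusters:
            assert len({comp_of[n] for n in cluster}) == 1

    def test_partition_type_rejects_overlap(self):
        with pytest.raises(ValueError):
            ClusterPartition((frozenset({"a", "b"}), frozenset({"b"})))
        with pytest.raises(ValueError):
            ClusterPartition((frozenset(),))


class TestOracleEquivalence:
    """Partitions equal an independently coded naive dense iteration."""

    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_exhaustive_small_graphs_per_edge_weights(self, n):
        nodes = [f"n{i}" for i in range(n)]
        slots = list(itertools.combinations(range(n), 2))
        for combo in itertools.product((0.0, 0.5, 1.0), repeat=len(slots)):
            edges = [(u, v, w) for (u, v), w in zip(slots, combo) if w]
            G = graph_from_edges(n, edges)
            part = mcl(G, inflation=1.7)
            oracle = oracles.mcl_reference(
                nodes, [(f"n{u}", f"n{v}", w) for u, v, w in edges],
                inflation=1.7)
            assert list(part.clusters) == oracle, f"n={n} edges={edges}"

    @pytest.mark.parametrize("weight", [0.5, 1.0])
    def test_exhaustive_five_node_topologies_uniform_weight(self, weight):
        nodes = [f"n{i}" for i in range(5)]
        slots = list(itertools.combinations(range(5), 2))
        for mask in range(1 << len(slots)):
            edges = [(u, v, weight) for k, (u, v) in enumerate(slots)
                     if mask >> k & 1]
            part = mcl(graph_from_edges(5, edges), inflation=1.5)
            oracle = oracles.mcl_reference(
                nodes, [(f"n{u}", f"n{v}", w) for u, v, w in edges],
                inflation=1.5)
            assert list(part.clusters) == oracle, f"mask={mask}"

    @pytest.mark.parametrize("inflation", [1.3, 1.8, 2.5])
    def test_random_six_node_weighted_graphs(self, inflation):
        rng = np.random.default_rng(int(inflation * 100))
        nodes = [f"n{i}" for i in range(6)]
        slots = list(itertools.combinations(range(6), 2))
        for _ in range(150):
            weights = rng.choice([0.0, 0.5, 1.0], size=len(slots),
                                 p=[0.5, 0.25, 0.25])
            edges = [(u, v, float(w)) for (u, v), w in zip(slots, weights) if w]
            part = mcl(graph_from_edges(6, edges), inflation=inflation)
            oracle = oracles.mcl_reference(
                nodes, [(f"n{u}", f"n{v}", w) for u, v, w in edges],
                inflation=inflation)
            assert list(part.clusters) == oracle
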