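"""Community detection and module-level metrics."""

import networkx as nx
import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import fconn
from fconn.community import (
    best_partition,
    greedy_modularity,
    hc_reference_partitions,
    modular_metrics,
    modularity,
    name_modules,
    participation_coefficient,
)
from fconn.network import BinaryGraph, binarize, group_occurrence_graph
from conftest import random_graph
from oracles import oracle_modularity, oracle_participation


def _graph(edges, n):
    adj = np.zeros((n, n), dtype=np.uint8)
    for i, j in edges:
        adj[i, j] = adj[j, i] = 1
    return BinaryGraph(adjacency=adj, sparsity=len(edges) / (n * (n - 1) / 2))


def _two_cliques(k=5):
    adj = np.zeros((2 * k, 2 * k), dtype=np.uint8)
    adj[:k, :k] = 1
    adj[k:, k:] = 1
    np.fill_diagonal(adj, 0)
    return BinaryGraph(adjacency=adj, sparsity=float(adj.sum() / (2 * k * (2 * k - 1))))


class TestGreedyModularity:
    def test_two_cliques_recovered_with_q_half(self):
        part = greedy_modularity(_two_cliques())
        assert part.n_modules == 2
        assert part.q == pytest.approx(0.5, abs=1e-12)
        assert len(set(part.labels[:5])) == 1 and len(set(part.labels[5:])) == 1

    def test_complete_graph_single_module(self):
        adj = np.ones((6, 6), dtype=np.uint8) - np.eye(6, dtype=np.uint8)
        part = greedy_modularity(BinaryGraph(adjacency=adj, sparsity=1.0))
        assert part.n_modules == 1
        assert part.q == pytest.approx(0.0, abs=1e-12)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            greedy_modularity(_graph([], 4))

    @pytest.mark.parametrize("seed", range(20))
    def test_planted_four_block_recovery(self, seed):
        g_rng = np.random.default_rng(seed)
        labels = np.repeat(np.arange(4), 10)
        a = g_rng.random((40, 40))
        p = np.where(labels[:, None] == labels[None, :], 0.9, 0.05)
        adj = ((a + a.T) / 2 < p).astype(np.uint8)
        np.fill_diagonal(adj, 0)
        part = greedy_modularity(
            BinaryGraph(adjacency=adj, sparsity=float(adj.sum() / (40 * 39)))
        )
        assert adjusted_rand_score(labels, part.labels) == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_q_consistent_with_definition_and_networkx(self, seed):
        g = random_graph(30, 0.2, seed)
        if g.n_edges == 0:
            return
        part = greedy_modularity(g)
        adj = np.asarray(g.adjacency)
        assert part.q == pytest.approx(modularity(adj, part.labels), abs=1e-12)
        assert part.q == pytest.approx(oracle_modularity(adj, part.labels), abs=1e-12)
        G = nx.from_numpy_array(adj)
        comms = [set(np.nonzero(part.labels == s)[0]) for s in np.unique(part.labels)]
        assert part.q == pytest.approx(
            nx.algorithms.community.modularity(G, comms), abs=1e-10
        )

    def test_isolated_nodes_become_singletons(self):
        g = _graph([(0, 1), (1, 2), (0, 2)], 5)
        part = greedy_modularity(g)
        assert part.labels[3] != part.labels[4]
        assert len(np.unique(part.labels)) == 3


class TestParticipation:
    def test_all_edges_within_module_zero(self):
        g = _two_cliques()
        labels = np.repeat([0, 1], 5)
        np.testing.assert_allclose(participation_coefficient(g.adjacency, labels), 0.0)

    def test_split_degree_two_node(self):
        g = _graph([(0, 1), (0, 2)], 3)
        labels = np.array([0, 1, 2])
        p = participation_coefficient(g.adjacency, labels)
        assert p[0] == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_oracle_and_relabeling_invariant(self, seed):
        g = random_graph(20, 0.3, seed)
        g_rng = np.random.default_rng(seed)
        labels = g_rng.integers(0, 4, 20)
        p = participation_coefficient(g.adjacency, labels)
        np.testing.assert_allclose(p, oracle_participation(np.asarray(g.adjacency), labels), atol=1e-12)
        relabeled = (labels + 7) * 3  # arbitrary injective relabeling
        np.testing.assert_allclose(
            p, participation_coefficient(g.adjacency, relabeled), atol=1e-12
        )


class TestModularMetrics:
    def test_single_module_degenerate_case(self):
        g = _two_cliques(3)
        part = fconn.ModularPartition(labels=np.zeros(6, dtype=int), q=0.0)
        mm = modular_metrics(g, part)
        assert mm.intra_conn.shape == (1,)
        density = g.n_edges / (6 * 5 / 2)
        assert mm.intra_conn[0] == pytest.approx(density, abs=1e-12)

    def test_single_node_module_zeroed(self):
        g = _graph([(0, 1), (1, 2), (0, 2)], 4)
        part = fconn.ModularPartition(labels=np.array([0, 0, 0, 1]), q=0.0)
        mm = modular_metrics(g, part)
        assert mm.within_degree[3] == 0.0 and mm.within_efficiency[3] == 0.0

    def test_mean_normalization_averages_to_one(self):
        g = _two_cliques()
        part = fconn.ModularPartition(labels=np.repeat([0, 1], 5), q=0.5)
        mm = modular_metrics(g, part)
        np.testing.assert_allclose(mm.within_degree, 1.0)

    def test_zscore_variant(self):
        g = _graph([(0, 1), (0, 2), (0, 3), (1, 2)], 4)
        part = fconn.ModularPartition(labels=np.zeros(4, dtype=int), q=0.0)
        mm = modular_metrics(g, part, normalization="zscore")
        assert mm.within_degree.mean() == pytest.approx(0.0, abs=1e-12)

    def test_weighted_intra_inter(self):
        g = _two_cliques(3)
        part = fconn.ModularPartition(labels=np.repeat([0, 1], 3), q=0.5)
        w = np.full((6, 6), 0.25)
        w[:3, :3] = 0.8
        w[3:, 3:] = 0.6
        np.fill_diagonal(w, 0.0)
        mm = modular_metrics(g, part, weights=w)
        assert mm.intra_conn[0] == pytest.approx(0.8, abs=1e-12)
        assert mm.intra_conn[1] == pytest.approx(0.6, abs=1e-12)
        assert mm.inter_conn[0, 1] == pytest.approx(0.25, abs=1e-12)

    def test_partition_must_cover_nodes(self):
        g = _two_cliques(3)
        part = fconn.ModularPartition(labels=np.zeros(4, dtype=int), q=0.0)
        with pytest.raises(ValueError, match="cover"):
            modular_metrics(g, part)


class TestHcReference:
    def test_identical_graphs_identical_partitions(self):
        g = _two_cliques()
        parts = hc_reference_partitions([g] * 5, taus=np.array([0.5, 0.6, 0.7]))
        assert len(parts) == 3
        for p in parts:
            np.testing.assert_array_equal(p.labels, parts[0].labels)
            assert p.q == pytest.approx(0.5, abs=1e-12)

    def test_tau_nesting_of_occurrence_graphs(self, rng):
        graphs = []
        for _ in range(9):
            z = rng.normal(size=(10, 10))
            z = (z + z.T) / 2
            np.fill_diagonal(z, 0)
            graphs.append(binarize(fconn.ConnectivityMatrix(z=z), 0.4))
        g70 = group_occurrence_graph(graphs, 0.70)
        g50 = group_occurrence_graph(graphs, 0.50)
        assert {tuple(e) for e in g70.edge_list()} <= {tuple(e) for e in g50.edge_list()}

    @pytest.mark.parametrize("seed", range(3))
    def test_seven_module_recovery_on_synthetic_controls(self, seed):
        """Occurrence graphs from simulated HC subjects recover the
        planted 7-module parcellation with exact sizes 50/50/48/21/22/27/28."""
        spec = fconn.CohortSpec(group_sizes={"HC": 43, "FCNAD": 1, "FCAD": 1}, seed=seed)
        records, ts_sets, motions = fconn.generate_cohort(spec)
        graphs = []
        for rec, ts, mot in zip(records, ts_sets, motions):
            if rec.group != "HC":
                continue
            cleaned, _ = fconn.clean_pipeline(ts, mot)
            graphs.append(binarize(fconn.correlation_matrix(cleaned), 0.20))
        parts = hc_reference_partitions(
            graphs,
            atlas_labels=spec.module_labels,
            atlas_names=list(spec.module_names),
        )
        best = best_partition(parts)
        assert best.n_modules == 7
        assert sorted(best.module_sizes().tolist()) == sorted(spec.module_sizes)
        assert set(best.module_names) == set(spec.module_names)
        assert best.q > 0.5

    def test_module_sizes_sum_to_n(self):
        for seed in range(5):
            g = random_graph(25, 0.25, seed)
            if g.n_edges == 0:
                continue
            part = greedy_modularity(g)
            assert part.module_sizes().sum() == 25


def test_name_modules_majority_overlap():
    part = fconn.ModularPartition(labels=np.array([0, 0, 0, 1, 1]), q=0.0)
    ref = np.array([2, 2, 1, 0, 0])
    names = name_modules(part, ref, ["alpha", "beta", "gamma"])
    assert names == ["gamma", "alpha"]
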