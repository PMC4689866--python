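"""Markov Clustering: closed-form cases, invariants, oracle agreement, sweep."""

import networkx as nx
import numpy as np
import pytest

import mybnet as m
from mybnet.mcl import _normalize_columns

from ._mcl_reference import partitions_agree, reference_mcl
from .conftest import random_correlation_matrix


def _net_from_graph(g: nx.Graph, r: float = 0.9) -> m.SignedNetwork:
    for _, _, d in g.edges(data=True):
        d.setdefault("r", r)
        d.setdefault("sign", "+")
    return m.SignedNetwork(graph=g, cutoff=0.85)


def _random_weighted_graph(n: int, p: float, seed: int) -> m.SignedNetwork:
    rng = np.random.default_rng(seed)
    g = nx.gnp_random_graph(n, p, seed=seed)
    for _, _, d in g.edges(data=True):
        d["r"] = float(rng.uniform(0.4, 1.0)) * rng.choice([1.0, -1.0])
        d["sign"] = "+" if d["r"] > 0 else "-"
    g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
    return m.SignedNetwork(graph=g, cutoff=0.0)


class TestRunMcl:
    def test_two_disjoint_triangles_give_two_modules(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c"),
                          ("x", "y"), ("y", "z"), ("x", "z")])
        part = m.run_mcl(_net_from_graph(g), m.MclParams(inflation=2.0))
        assert part.n_modules() == 2
        assert not part.unassigned
        assert {frozenset(v) for v in part.modules.values()} == \
            {frozenset("abc"), frozenset("xyz")}

    @pytest.mark.parametrize("inflation", [1.2, 2.0, 3.0])
    def test_single_clique_is_one_module(self, inflation):
        g = nx.complete_graph(5)
        part = m.run_mcl(_net_from_graph(nx.relabel_nodes(g, str)),
                         m.MclParams(inflation=inflation))
        assert part.n_modules() == 1
        assert len(next(iter(part.modules.values()))) == 5

    def test_small_component_filtered_to_unassigned(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c"), ("p", "q")])
        part = m.run_mcl(_net_from_graph(g))
        assert part.unassigned == frozenset({"p", "q"})
        assert part.modules == {1: frozenset("abc")}

    def test_partition_covers_node_set(self):
        net = _random_weighted_graph(40, 0.1, seed=5)
        part = m.run_mcl(net)
        assert part.covered_nodes() == frozenset(net.graph.nodes)

    def test_deterministic(self):
        net = _random_weighted_graph(35, 0.15, seed=6)
        a = m.run_mcl(net)
        b = m.run_mcl(net)
        assert a.modules == b.modules and a.unassigned == b.unassigned

    def test_clusters_never_span_components(self):
        for seed in range(5):
            net = _random_weighted_graph(40, 0.06, seed=seed)
            part = m.run_mcl(net)
            comp_of = {}
            for k, comp in enumerate(nx.connected_components(net.graph)):
                for node in comp:
                    comp_of[node] = k
            for genes in part.modules.values():
                assert len({comp_of[g] for g in genes}) == 1

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            m.run_mcl(m.SignedNetwork(graph=nx.Graph(), cutoff=0.85))

    def test_invalid_inflation_rejected(self):
        with pytest.raises(ValueError, match="inflation"):
            m.MclParams(inflation=1.0)


def test_column_stochastic_after_every_step():
    """The transition matrix keeps unit column sums through expansion,
    inflation and pruning."""
    rng = np.random.default_rng(7)
    a = rng.uniform(0, 1, (20, 20))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    mat = _normalize_columns(a)
    for _ in range(10):
        mat = np.linalg.matrix_power(mat, 2)
        mat = _normalize_columns(np.power(mat, 2.0))
        mat[mat < 1e-6] = 0.0
        mat = _normalize_columns(mat)
        assert np.allclose(mat.sum(axis=0), 1.0, atol=1e-9)


def test_agreement_with_independent_reference():
    """In-house MCL matches a naive independent implementation on random
    weighted graphs, up to the minimum-size filter."""
    for seed in range(8):
        net = _random_weighted_graph(30 + 3 * seed, 0.12, seed=100 + seed)
        nodes = sorted(net.graph.nodes)
        idx = {g: i for i, g in enumerate(nodes)}
        adj = np.zeros((len(nodes), len(nodes)))
        for u, v, d in net.graph.edges(data=True):
            adj[idx[u], idx[v]] = adj[idx[v], idx[u]] = abs(d["r"])
        ref = [{nodes[i] for i in c} for c in reference_mcl(adj, 2.0)]
        part = m.run_mcl(net, m.MclParams(inflation=2.0))
        mine = [set(v) for v in part.modules.values()]
        mine += [[g] for g in part.unassigned]  # restore filtered singletons
        assert partitions_agree(mine, ref, min_size=3), f"seed {seed}"


class TestModularity:
    def test_two_cliques_correctly_partitioned(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        g = nx.relabel_nodes(g, str)
        net = _net_from_graph(g)
        part = m.ModulePartition(
            modules={1: frozenset(map(str, range(4))),
                     2: frozenset(map(str, range(4, 8)))},
            inflation_used=2.0, unassigned=frozenset())
        assert m.modularity(net, part) == pytest.approx(0.5)

    def test_single_community_is_zero(self):
        g = nx.relabel_nodes(nx.complete_graph(5), str)
        part = m.ModulePartition(modules={1: frozenset(map(str, range(5)))},
                                 inflation_used=2.0, unassigned=frozenset())
        assert m.modularity(_net_from_graph(g), part) == pytest.approx(0.0)

    def test_random_partition_within_known_bounds(self):
        rng = np.random.default_rng(8)
        for seed in range(5):
            net = _random_weighted_graph(25, 0.2, seed=seed)
            nodes = sorted(net.graph.nodes)
            rng.shuffle(nodes)
            half = len(nodes) // 2
            part = m.ModulePartition(modules={1: frozenset(nodes[:half]),
                                              2: frozenset(nodes[half:])},
                                     inflation_used=2.0, unassigned=frozenset())
            q = m.modularity(net, part)
            assert -0.5 <= q <= 1.0

    def test_empty_edge_set_undefined(self):
        g = nx.Graph()
        g.add_nodes_from("ab")
        part = m.ModulePartition(modules={}, inflation_used=2.0,
                                 unassigned=frozenset("ab"))
        assert m.modularity(m.SignedNetwork(graph=g, cutoff=0.5), part) is None


class TestInflationSweep:
    def test_single_value_grid_returned(self, default_dataset, default_network):
        _, _, annotations, _, _ = default_dataset
        _, net = default_network
        best, table = m.inflation_sweep(net, annotations, I_values=[1.8])
        assert best.inflation_used == 1.8
        assert len(table) == 1

    def test_unusable_partition_scores_zero(self):
        # a single clique can only yield one module -> F recorded as 0
        g = nx.relabel_nodes(nx.complete_graph(5), lambda i: f"g{i}")
        net = _net_from_graph(g)
        ann = m.AnnotationMap(term_to_genes={"T": frozenset({"g0", "g1"})},
                              universe=frozenset(g.nodes))
        best, table = m.inflation_sweep(net, ann, I_values=[2.0])
        assert table["f_measure"].iloc[0] == 0.0

    def test_fragmentation_tendency_with_inflation(self):
        """Higher inflation tends to retain at least as many modules
        (majority vote over random geometric graphs; a tendency, not a
        theorem)."""
        wins = 0
        trials = 15
        for seed in range(trials):
            g = nx.random_geometric_graph(45, 0.22, seed=seed)
            g = nx.relabel_nodes(g, lambda i: f"g{i:02d}")
            net = _net_from_graph(g)
            lo = m.run_mcl(net, m.MclParams(inflation=1.4)).n_modules()
            hi = m.run_mcl(net, m.MclParams(inflation=3.0)).n_modules()
            wins += hi >= lo
        assert wins > trials / 2
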