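import numpy as np
import pandas as pd
import pytest
import networkx as nx
from dataclasses import replace

from conftest import brute_force_maximal_cliques, random_graph
from pbmcnet.correlation import CorrelationResult, correlation_matrix
from pbmcnet.model import ModuleNetworkModel
from pbmcnet.network import (
    CoexpressionGraph,
    build_graph,
    hierarchy_signature,
    identify_hubs,
    maximal_cliques,
    merge_modules,
    node_connectivity,
)
from pbmcnet.qpcr import quantify
from pbmcnet.simulate import default_control_spec, generate_cohort


def corr_from_weights(genes, weights, default=0.0):
    """CorrelationResult with prescribed |r| entries (others = default)."""
    G = len(genes)
    r = pd.DataFrame(np.full((G, G), default), index=genes, columns=genes)
    np.fill_diagonal(r.values, 1.0)
    for (a, b), w in weights.items():
        r.loc[a, b] = r.loc[b, a] = w
    p = pd.DataFrame(np.zeros((G, G)), index=genes, columns=genes)
    n = pd.DataFrame(np.full((G, G), 30), index=genes, columns=genes)
    return CorrelationResult(r, p, p.copy(), n, G * (G - 1) // 2)


def graph_from_adj(adj):
    g = nx.Graph()
    g.add_nodes_from(adj)
    for a, nbrs in adj.items():
        for b in nbrs:
            g.add_edge(a, b, weight=0.9)
    return CoexpressionGraph(g, tau=0.7)


class TestBuildGraph:
    def test_strict_threshold(self):
        c = corr_from_weights(["A", "B", "C"],
                              {("A", "B"): 0.71, ("B", "C"): 0.70})
        g = build_graph(c, tau=0.7)
        assert g.graph.has_edge("A", "B")          # 0.71 > 0.7
        assert not g.graph.has_edge("B", "C")      # strict: 0.70 is excluded
        assert g.graph.edges["A", "B"]["weight"] == pytest.approx(0.71)

    def test_negative_correlations_count_by_magnitude(self):
        c = corr_from_weights(["A", "B"], {("A", "B"): -0.9})
        assert build_graph(c, 0.7).graph.has_edge("A", "B")

    def test_tau_zero_gives_complete_graph(self):
        c = corr_from_weights(["A", "B", "C"],
                              {("A", "B"): 0.2, ("B", "C"): 0.3, ("A", "C"): 0.4})
        g = build_graph(c, tau=0.0)
        assert g.graph.number_of_edges() == 3

    def test_tau_out_of_range(self):
        c = corr_from_weights(["A", "B"], {})
        with pytest.raises(ValueError):
            build_graph(c, tau=1.0)


class TestMaximalCliques:
    def test_triangle(self):
        g = graph_from_adj({"A": {"B", "C"}, "B": {"A", "C"}, "C": {"A", "B"}})
        assert maximal_cliques(g) == [frozenset("ABC")]

    def test_path(self):
        g = graph_from_adj({"A": {"B"}, "B": {"A", "C"}, "C": {"B"}})
        assert maximal_cliques(g) == [frozenset("AB"), frozenset("BC")]

    def test_empty_graph(self):
        g = CoexpressionGraph(nx.Graph(), tau=0.7)
        assert maximal_cliques(g) == []

    def test_matches_brute_force_and_networkx(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(4, 13))
            nodes, adj = random_graph(rng, n, 0.5)
            g = graph_from_adj(adj)
            ours = maximal_cliques(g)
            oracle = brute_force_maximal_cliques(nodes, adj)
            assert ours == oracle
            nx_cliques = sorted(
                {frozenset(c) for c in nx.find_cliques(g.graph)},
                key=lambda s: (-len(s), tuple(sorted(s))),
            )
            assert ours == nx_cliques


class TestMergeModules:
    def test_overlapping_triangles_merge(self):
        genes = list("ABCD")
        weights = {(a, b): 0.9 for a, b in
                   [("A", "B"), ("A", "C"), ("B", "C"), ("B", "D"), ("C", "D")]}
        # A-D below the edge threshold but high enough for the mean-|r| floor
        c = corr_from_weights(genes, weights, default=0.5)
        g = build_graph(c, 0.7)
        cliques = maximal_cliques(g)
        mods = merge_modules(cliques, c, g, gamma=0.8, alpha_corr=0.8)
        assert len(mods) == 1
        assert mods[0].members == ("A", "B", "C", "D")
        assert mods[0].density == pytest.approx(5 / 6)

    def test_disjoint_triangles_stay_separate(self):
        genes = list("ABCDEF")
        tri = [("A", "B"), ("A", "C"), ("B", "C"),
               ("D", "E"), ("D", "F"), ("E", "F")]
        c = corr_from_weights(genes, {e: 0.9 for e in tri}, default=0.1)
        g = build_graph(c, 0.7)
        mods = merge_modules(maximal_cliques(g), c, g)
        assert [m.members for m in mods] == [("A", "B", "C"), ("D", "E", "F")]

    def test_disjoint_union_of_cliques_returned_exactly(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            sizes = rng.integers(2, 5, size=3)
            genes, weights, start = [], {}, 0
            blocks = []
            for s in sizes:
                block = [f"g{start + i}" for i in range(s)]
                start += s
                genes += block
                blocks.append(tuple(sorted(block)))
                for i, a in enumerate(block):
                    for b in block[i + 1:]:
                        weights[(a, b)] = 0.75 + 0.2 * rng.random()
            c = corr_from_weights(genes, weights, default=0.0)
            g = build_graph(c, 0.7)
            mods = merge_modules(maximal_cliques(g), c, g, alpha_corr=0.0)
            assert sorted(m.members for m in mods) == sorted(blocks)

    def test_contained_subnetworks_absorbed(self):
        genes = list("ABCD")
        c = corr_from_weights(genes, {}, default=0.9)
        g = build_graph(c, 0.7)
        mods = merge_modules(
            [frozenset("AB"), frozenset("ABCD")], c, g)
        assert [m.members for m in mods] == [("A", "B", "C", "D")]

    def test_floors_enforced_on_returned_modules(self):
        # a raw clique whose mean |r| sits between tau and alpha_corr is
        # not reported as a module
        c = corr_from_weights(list("ABC"), {("A", "B"): 0.72, ("A", "C"): 0.73,
                                            ("B", "C"): 0.71}, default=0.0)
        g = build_graph(c, 0.7)
        mods = merge_modules(maximal_cliques(g), c, g, gamma=0.8, alpha_corr=0.8)
        assert mods == []
        kept = merge_modules(maximal_cliques(g), c, g, gamma=0.8, alpha_corr=0.0)
        assert len(kept) == 1

    def test_deterministic_under_input_order(self, control_rcn):
        c = correlation_matrix(control_rcn)
        g = build_graph(c, 0.7)
        cliques = maximal_cliques(g)
        a = merge_modules(cliques, c, g)
        b = merge_modules(list(reversed(cliques)), c, g)
        assert [m.members for m in a] == [m.members for m in b]

    def test_unknown_node_is_error(self):
        c = corr_from_weights(list("AB"), {("A", "B"): 0.9})
        g = build_graph(c, 0.7)
        with pytest.raises(ValueError, match="absent"):
            merge_modules([frozenset(["A", "Z"])], c, g)


class TestNodeConnectivity:
    def test_complete_graph(self):
        adj = {v: {u for u in "ABCDE" if u != v} for v in "ABCDE"}
        conn = node_connectivity(graph_from_adj(adj), "ABCDE")
        assert all(kc == (4, 1.0) for kc in conn.values())

    def test_star_center(self):
        adj = {"C": {"A", "B", "D", "E"}, "A": {"C"}, "B": {"C"},
               "D": {"C"}, "E": {"C"}}
        conn = node_connectivity(graph_from_adj(adj), adj.keys())
        assert conn["C"] == (4, 0.0)
        assert conn["A"] == (1, 0.0)

    def test_matches_networkx_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            nodes, adj = random_graph(rng, 10, 0.4)
            g = graph_from_adj(adj)
            conn = node_connectivity(g, nodes)
            nx_c = nx.clustering(g.graph)
            for v in nodes:
                k, ck = conn[v]
                assert k == g.graph.degree[v]
                assert ck == pytest.approx(nx_c[v], abs=1e-12)


class TestHierarchySignature:
    def test_exact_inverse_power_law(self):
        assert hierarchy_signature([(2, 1.0), (4, 0.5), (8, 0.25)]) == pytest.approx(-1.0)

    def test_flat_complete_graph(self):
        assert hierarchy_signature([(3, 1.0), (5, 1.0), (9, 1.0)]) == pytest.approx(0.0)

    def test_undefined_cases(self):
        assert hierarchy_signature([(4, 0.0), (5, 0.0)]) is None
        assert hierarchy_signature([(4, 0.5), (4, 0.7)]) is None

    def test_bridged_cliques_are_hierarchical(self):
        # two K4s joined through one bridge node: clique members keep C=1
        # while the high-degree bridge has low clustering -> negative slope
        adj = {v: set() for v in "ABCDEFGH"} | {"X": set()}
        for block in ("ABCD", "EFGH"):
            for i, a in enumerate(block):
                for b in block[i + 1:]:
                    adj[a].add(b); adj[b].add(a)
                adj[a].add("X"); adj["X"].add(a)
        g = graph_from_adj(adj)
        conn = node_connectivity(g, adj.keys())
        nx_c = nx.clustering(g.graph)   # independent oracle
        for v, (k, ck) in conn.items():
            assert ck == pytest.approx(nx_c[v], abs=1e-12)
        slope = hierarchy_signature(conn.values())
        assert slope is not None and slope < 0


class TestIdentifyHubs:
    def test_internal_node_without_external_edge_is_not_hub(self):
        adj = {v: {u for u in "ABC" if u != v} for v in "ABC"}
        g = graph_from_adj(adj)
        mods = merge_modules(maximal_cliques(g),
                             corr_from_weights(list("ABC"), {}, default=0.9), g)
        hubs = identify_hubs(g, mods)
        assert hubs[0] == ()

    def test_bridge_node_is_hub(self):
        adj = {v: {u for u in "ABC" if u != v} for v in "ABC"}
        adj |= {v: {u for u in "DEF" if u != v} for v in "DEF"}
        adj["A"].add("D"); adj["D"].add("A")
        g = graph_from_adj(adj)
        c = corr_from_weights(list("ABCDEF"), {}, default=0.9)
        mods = merge_modules([frozenset("ABC"), frozenset("DEF")], c, g)
        hubs = identify_hubs(g, mods)
        flat = {h for hs in hubs.values() for h in hs}
        assert flat == {"A", "D"}

    def test_empty_module_list_is_error(self):
        g = graph_from_adj({"A": set()})
        with pytest.raises(ValueError):
            identify_hubs(g, [])

    def test_planted_bridge_genes_recovered(self):
        # two designated module-1 genes loaded on both latent factors act
        # as bridges; at a cohort size where the adjacency concentrates
        # they are the only hubs of the cardiovascular module
        spec = replace(
            default_control_spec(seed=2),
            n_subjects=200,
            module_factor_corr=0.5,
            hub_genes=("KDR", "NES"),
            hub_primary_loading=1.0,
            hub_cross_loading=0.5,
            module1_phenotype_couplings={},
        )
        cq, _ = generate_cohort(spec)
        res = ModuleNetworkModel.from_cq(cq).fit()
        m1_modules = [
            m for m in res.modules
            if len(set(m.members) & set(spec.panel.module1)) >= len(m) / 2
        ]
        assert m1_modules
        hubs = {h for m in m1_modules for h in m.hubs}
        assert hubs == {"KDR", "NES"}
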