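"""Network construction, centrality, and hub/bottleneck role calls."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from comorbnet import network as net
from comorbnet.errors import ValidationError
from comorbnet.io import GeneSet, InteractionRecord
from oracles import brute_force_betweenness

R = InteractionRecord


class TestBuildNetwork:
    def test_canonicalization(self):
        records = [R("A", "A", 1.0), R("A", "B", 0.9), R("B", "A", 0.7)]
        G = net.build_network(records, 0.4)
        assert set(G.nodes) == {"A", "B"}
        assert G.number_of_edges() == 1
        assert G["A"]["B"]["weight"] == 0.9

    def test_all_below_cutoff_gives_empty_network(self):
        G = net.build_network([R("A", "B", 0.2), R("B", "C", 0.3)], 0.5)
        assert G.number_of_nodes() == 0

    def test_string_score_scale(self):
        G = net.build_network([R("A", "B", 900)], 0.4, score_scale=1000)
        assert G["A"]["B"]["weight"] == 0.9

    def test_isolated_genes_excluded(self):
        # C's only record is a self-loop: it vanishes from the node set
        G = net.build_network([R("A", "B", 0.9), R("C", "C", 1.0)], 0.1)
        assert set(G.nodes) == {"A", "B"}

    @given(
        scores=st.lists(st.floats(0, 1), min_size=1, max_size=30),
        cut1=st.floats(0, 1),
        cut2=st.floats(0, 1),
    )
    def test_raising_cutoff_is_monotone(self, scores, cut1, cut2):
        records = [R(f"N{i}", f"N{(i * 7 + 1) % 20}", s) for i, s in enumerate(scores)]
        lo, hi = min(cut1, cut2), max(cut1, cut2)
        G_lo, G_hi = net.build_network(records, lo), net.build_network(records, hi)
        assert G_hi.number_of_nodes() <= G_lo.number_of_nodes()
        assert G_hi.number_of_edges() <= G_lo.number_of_edges()


class TestInducedSubgraph:
    def test_identity_and_empty(self):
        G = nx.complete_graph(4)
        G = nx.relabel_nodes(G, {i: f"N{i}" for i in G.nodes})
        full = net.induced_subgraph(G, GeneSet("all", frozenset(G.nodes)))
        assert set(full.edges()) == set(G.edges())
        empty = net.induced_subgraph(G, GeneSet("none", frozenset({"X", "Y"})))
        assert empty.number_of_nodes() == 0

    def test_k4_on_three_nodes_is_k3(self):
        G = nx.relabel_nodes(nx.complete_graph(4), {i: f"N{i}" for i in range(4)})
        H = net.induced_subgraph(G, GeneSet("three", frozenset({"N0", "N1", "N2"})))
        assert H.number_of_nodes() == 3 and H.number_of_edges() == 3


class TestCentrality:
    def test_path_and_star(self):
        path = nx.Graph([("A", "B"), ("B", "C")])
        tab = net.centrality(path)
        assert tab.table.at["B", "betweenness"] == 1.0
        assert tab.table.at["A", "betweenness"] == 0.0

        star = nx.star_graph(3)
        star = nx.relabel_nodes(star, {0: "C", 1: "L1", 2: "L2", 3: "L3"})
        assert net.centrality(star).table.at["C", "betweenness"] == 1.0

    def test_tiny_networks_have_zero_betweenness(self):
        G = nx.Graph([("A", "B")])
        assert (net.centrality(G).table["betweenness"] == 0).all()

    def test_degree_sum_conservation(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            G = nx.gnp_random_graph(15, 0.3, seed=int(rng.integers(2**31)))
            G = nx.relabel_nodes(G, {i: f"N{i:02d}" for i in G.nodes})
            tab = net.centrality(G)
            assert tab.table["degree"].sum() == 2 * G.number_of_edges()

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            G = nx.gnp_random_graph(8, 0.4, seed=int(rng.integers(2**31)))
            G = nx.relabel_nodes(G, {i: f"N{i}" for i in G.nodes})
            tab = net.centrality(G)
            oracle = brute_force_betweenness(G)
            for v in G:
                assert tab.table.at[v, "betweenness"] == pytest.approx(oracle[v], abs=1e-12)


class TestRoleCalls:
    def test_regular_graph_has_no_hubs(self):
        G = nx.cycle_graph(10)
        G = nx.relabel_nodes(G, {i: f"N{i}" for i in G.nodes})
        assert net.call_hubs(net.centrality(G)) == frozenset()

    def test_star_hub_threshold(self):
        star = nx.star_graph(10)
        star = nx.relabel_nodes(star, {i: ("C" if i == 0 else f"L{i:02d}") for i in star.nodes})
        tab = net.centrality(star)
        assert tab.mean_degree == pytest.approx(20 / 11)
        assert tab.sd_degree == pytest.approx(2.587, abs=1e-3)
        assert net.call_hubs(tab) == frozenset({"C"})

    def test_sample_sd_option(self):
        star = nx.relabel_nodes(nx.star_graph(10), {i: f"N{i:02d}" for i in range(11)})
        pop = net.centrality(star, ddof=0)
        samp = net.centrality(star, ddof=1)
        assert samp.sd_degree > pop.sd_degree

    def test_top_five_percent_of_99_is_5(self):
        G = nx.path_graph(99)
        G = nx.relabel_nodes(G, {i: f"N{i:02d}" for i in G.nodes})
        tab = net.centrality(G)
        assert len(net.call_bottlenecks(tab, 0.05)) == 5

    def test_exact_integer_fraction_is_not_inflated(self):
        # IEEE 0.05*100 rounds just above 5; the call must still return 5
        G = nx.relabel_nodes(nx.path_graph(100), {i: f"N{i:03d}" for i in range(100)})
        assert len(net.call_bottlenecks(net.centrality(G), 0.05)) == 5

    def test_single_node_is_degenerate_bottleneck(self):
        G = nx.Graph()
        G.add_edge("A", "B")
        tab = net.centrality(net.induced_subgraph(G, GeneSet("s", frozenset({"A", "B"}))))
        assert len(net.call_bottlenecks(tab, 0.05)) == 1  # ceil(0.05*2) = 1

    def test_bottleneck_tie_break_is_lexicographic(self):
        G = nx.relabel_nodes(nx.cycle_graph(6), {i: f"N{i}" for i in range(6)})
        tab = net.centrality(G)  # all betweenness equal
        assert net.call_bottlenecks(tab, 0.34) == frozenset({"N0", "N1", "N2"})

    def test_hub_call_invariant_under_relabeling(self):
        G = nx.gnp_random_graph(20, 0.2, seed=7)
        G = nx.relabel_nodes(G, {i: f"N{i:02d}" for i in G.nodes})
        hubs = net.call_hubs(net.centrality(G))
        mapping = {f"N{i:02d}": f"Z{19 - i:02d}" for i in range(20)}
        hubs_relabeled = net.call_hubs(net.centrality(nx.relabel_nodes(G, mapping)))
        assert {mapping[h] for h in hubs} == set(hubs_relabeled)

    def test_invalid_fraction_rejected(self):
        G = nx.Graph([("A", "B")])
        with pytest.raises(ValidationError):
            net.call_bottlenecks(net.centrality(G), 0.0)


class TestRoleBundles:
    def test_call_roles_intersection(self):
        star = nx.relabel_nodes(nx.star_graph(10), {i: f"N{i:02d}" for i in range(11)})
        roles = net.call_roles(net.centrality(star))
        assert roles.hub_bottlenecks == roles.hubs & roles.bottlenecks
        assert roles.bottleneck_rank_cutoff == 1

    @pytest.mark.parametrize(
        "hubs_b,bottlenecks_b,expect_hubs,expect_bottlenecks",
        [
            ({"A", "B"}, {"C"}, {"A", "B"}, {"C"}),  # identical
            (set(), set(), set(), set()),  # disjoint
        ],
    )
    def test_shared_roles(self, hubs_b, bottlenecks_b, expect_hubs, expect_bottlenecks):
        a = net.roles_from_lists({"A", "B"}, {"C"})
        b = net.roles_from_lists(hubs_b, bottlenecks_b)
        sh, sb = net.shared_roles(a, b)
        assert sh == frozenset(expect_hubs)
        assert sb == frozenset(expect_bottlenecks)

    def test_key_genes_union_and_flags(self):
        call = net.roles_from_lists({"H1", "H2", "X"}, {"X", "B1"})
        kg = net.key_genes(call, frozenset({"H1", "X"}), frozenset({"B1"}))
        assert list(kg.index) == ["B1", "H1", "H2", "X"]
        assert kg.at["X", "is_hub"] and kg.at["X", "is_bottleneck"]
        assert kg.at["H1", "in_shared_hubs"] and not kg.at["H2", "in_shared_hubs"]
        assert kg.at["B1", "in_shared_bottlenecks"]

    def test_key_genes_degenerate_cases(self):
        empty = net.roles_from_lists(set(), set())
        assert len(net.key_genes(empty)) == 0
        nested = net.roles_from_lists({"A"}, {"A", "B"})  # hubs subset of bottlenecks
        assert list(net.key_genes(nested).index) == ["A", "B"]
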