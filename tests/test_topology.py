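import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netonco.topology import (
    betweenness,
    build_profile,
    classify_hubs,
    clustering_coefficients,
    cspd,
    degree_distribution,
    degrees,
    gspd,
    mean_degree,
    shortest_path_lengths,
)

import oracles
from conftest import make_net, make_set, random_edges

STAR5 = [("C0", f"L{i}") for i in range(4)]  # center + 4 leaves
TRIANGLE = [("A", "B"), ("B", "C"), ("A", "C")]
PATH3 = [("A", "B"), ("B", "C")]


@st.composite
def small_graphs(draw):
    n = draw(st.integers(min_value=2, max_value=8))
    nodes = [f"N{i}" for i in range(n)]
    all_pairs = list(itertools.combinations(nodes, 2))
    edges = draw(st.lists(st.sampled_from(all_pairs), min_size=1, max_size=len(all_pairs), unique=True))
    return nodes, edges


class TestDegrees:
    def test_star(self):
        deg = degrees(make_net(STAR5))
        assert deg["C0"] == 4
        assert all(deg[f"L{i}"] == 1 for i in range(4))

    def test_triangle(self):
        assert set(degrees(make_net(TRIANGLE)).values()) == {2}

    def test_matches_edge_scan(self, rng):
        nodes, edges = random_edges(rng, 30)
        net = make_net(edges, isolated=[v for v in nodes if not any(v in e for e in edges)])
        assert degrees(net) == oracles.bf_degrees(nodes, edges)


class TestMeanDegree:
    def test_254_nodes_595_edges_gives_4_69(self, rng):
        # any graph with these counts: mean degree is purely combinatorial
        from netonco.nullmodel import er_gnm
        from netonco.interactome import Interactome

        net = Interactome(er_gnm(254, 595, seed=rng))
        assert round(mean_degree(net), 2) == 4.69

    def test_edgeless(self):
        net = make_net([("A", "B")])
        net.graph.remove_edge("A", "B")
        assert mean_degree(net) == 0.0

    def test_k4(self):
        edges = list(itertools.combinations("ABCD", 2))
        assert mean_degree(make_net(edges)) == 3.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            mean_degree([])


class TestDegreeDistribution:
    def test_star(self):
        dist = degree_distribution(degrees(make_net(STAR5)).values())
        assert dist == {1: 0.8, 4: 0.2}

    def test_ring(self):
        ring = [(f"R{i}", f"R{(i + 1) % 6}") for i in range(6)]
        assert degree_distribution(degrees(make_net(ring)).values()) == {2: 1.0}

    def test_sums_to_one_and_matches_tally(self, rng):
        nodes, edges = random_edges(rng, 40)
        deg = oracles.bf_degrees(nodes, edges)
        dist = degree_distribution(deg.values())
        assert abs(sum(dist.values()) - 1.0) < 1e-12
        for k, p in dist.items():
            assert p == sum(1 for v in deg.values() if v == k) / len(nodes)

    def test_mean_of_distribution_equals_mean_degree(self, rng):
        nodes, edges = random_edges(rng, 25)
        deg = list(oracles.bf_degrees(nodes, edges).values())
        dist = degree_distribution(deg)
        assert sum(k * p for k, p in dist.items()) == pytest.approx(mean_degree(deg))


class TestClustering:
    def test_triangle_all_one(self):
        assert all(c == 1.0 for c in clustering_coefficients(make_net(TRIANGLE)).values())

    def test_star_center_zero_leaves_undefined(self):
        C = clustering_coefficients(make_net(STAR5))
        assert C["C0"] == 0.0
        assert all(math.isnan(C[f"L{i}"]) for i in range(4))

    def test_k4_minus_edge(self):
        edges = [e for e in itertools.combinations("ABCD", 2) if e != ("A", "B")]
        C = clustering_coefficients(make_net(edges))
        expected = oracles.bf_clustering("ABCD", edges)
        assert C["A"] == expected["A"] == 1.0  # degree-2 corners
        assert C["C"] == pytest.approx(2 / 3)
        assert C["D"] == pytest.approx(2 / 3)

    def test_tree_clustering_zero(self):
        tree = [("A", "B"), ("B", "C"), ("B", "D"), ("D", "E")]
        C = clustering_coefficients(make_net(tree))
        for v, c in C.items():
            if not math.isnan(c):
                assert c == 0.0


class TestBetweenness:
    def test_path(self):
        B = betweenness(make_net(PATH3))
        assert B == {"A": 0.0, "B": 1.0, "C": 0.0}

    def test_star_center(self):
        B = betweenness(make_net(STAR5))
        assert B["C0"] == 6.0  # C(4,2)

    def test_five_cycle(self):
        cyc = [(f"V{i}", f"V{(i + 1) % 5}") for i in range(5)]
        B = betweenness(make_net(cyc))
        assert all(b == pytest.approx(1.0) for b in B.values())

    def test_raw_count_on_diamond(self):
        # two shortest A-D paths (via B and via C): raw counts 1 each,
        # pair-dependency 0.5 each
        edges = [("A", "B"), ("A", "C"), ("B", "D"), ("C", "D")]
        net = make_net(edges)
        assert betweenness(net, "raw-count")["B"] == 1.0
        assert betweenness(net)["B"] == 0.5

    def test_unknown_variant(self):
        with pytest.raises(ValueError):
            betweenness(make_net(PATH3), "eigen")


@settings(max_examples=50, deadline=None)
@given(small_graphs())
def test_betweenness_matches_path_enumeration(graph):
    nodes, edges = graph
    net = make_net(edges, isolated=[v for v in nodes if not any(v in e for e in edges)])
    for variant in ("pair-dependency", "raw-count"):
        got = betweenness(net, variant)
        want = oracles.bf_betweenness(nodes, edges, variant)
        for v in nodes:
            assert got[v] == pytest.approx(want[v], abs=1e-9), (variant, v, edges)


@settings(max_examples=50, deadline=None)
@given(small_graphs())
def test_clustering_matches_neighbor_enumeration(graph):
    nodes, edges = graph
    net = make_net(edges, isolated=[v for v in nodes if not any(v in e for e in edges)])
    got = clustering_coefficients(net)
    want = oracles.bf_clustering(nodes, edges)
    for v in nodes:
        if math.isnan(want[v]):
            assert math.isnan(got[v])
        else:
            assert got[v] == pytest.approx(want[v])


@settings(max_examples=50, deadline=None)
@given(small_graphs())
def test_betweenness_conservation_small(graph):
    nodes, edges = graph
    net = make_net(edges, isolated=[v for v in nodes if not any(v in e for e in edges)])
    total = sum(betweenness(net).values())
    assert total == pytest.approx(oracles.bf_pair_distance_sum(nodes, edges), abs=1e-9)


class TestShortestPaths:
    def test_path_from_a(self):
        assert shortest_path_lengths(make_net(PATH3), "A") == {"A": 0, "B": 1, "C": 2}

    def test_disconnected(self):
        net = make_net([("A", "B"), ("C", "D")])
        assert shortest_path_lengths(net, "A") == {"A": 0, "B": 1}

    def test_missing_source(self):
        with pytest.raises(ValueError):
            shortest_path_lengths(make_net(PATH3), "Z")

    def test_matches_floyd_warshall(self, rng):
        nodes, edges = random_edges(rng, 30, p=0.1)
        net = make_net(edges, isolated=[v for v in nodes if not any(v in e for e in edges)])
        want = oracles.bf_all_pairs(nodes, edges)
        for source in nodes[:10]:
            assert shortest_path_lengths(net, source) == want[source]


class TestSetDistances:
    def test_gspd_k4_singleton(self):
        net = make_net(list(itertools.combinations("ABCD", 2)))
        per, avg = gspd(net, make_set({"A"}))
        assert per["A"] == 1.0 and avg == 1.0

    def test_gspd_path(self):
        per, avg = gspd(make_net(PATH3), make_set({"A"}))
        assert per["A"] == pytest.approx(1.5)

    def test_gspd_set_covers_network(self):
        net = make_net(TRIANGLE)
        with pytest.raises(ValueError, match="covers"):
            gspd(net, make_set({"A", "B", "C"}))

    def test_cspd_k4_pair(self):
        net = make_net(list(itertools.combinations("ABCD", 2)))
        per, avg = cspd(net, make_set({"A", "B"}))
        assert per == {"A": 1.0, "B": 1.0} and avg == 1.0

    def test_cspd_path_ends(self):
        per, _ = cspd(make_net(PATH3), make_set({"A", "C"}))
        assert per == {"A": 2.0, "C": 2.0}

    def test_cspd_needs_two(self):
        with pytest.raises(ValueError):
            cspd(make_net(PATH3), make_set({"A"}))


@settings(max_examples=50, deadline=None)
@given(small_graphs(), st.data())
def test_set_distances_match_double_loop(graph, data):
    nodes, edges = graph
    members = data.draw(
        st.lists(st.sampled_from(nodes), min_size=1, max_size=len(nodes), unique=True)
    )
    net = make_net(edges, isolated=[v for v in nodes if not any(v in e for e in edges)])
    pset = make_set(members)
    if set(nodes) - set(members):
        got, _ = gspd(net, pset)
        want = oracles.bf_gspd(nodes, edges, members)
        for v in members:
            if math.isnan(want[v]):
                assert math.isnan(got[v])
            else:
                assert got[v] == pytest.approx(want[v])
    if len(members) >= 2:
        got, _ = cspd(net, pset)
        want = oracles.bf_cspd(nodes, edges, members)
        for v in members:
            if math.isnan(want[v]):
                assert math.isnan(got[v])
            else:
                assert got[v] == pytest.approx(want[v])


class TestCompleteGraphIdentities:
    def test_k6(self):
        edges = list(itertools.combinations([f"K{i}" for i in range(6)], 2))
        net = make_net(edges)
        assert all(c == 1.0 for c in clustering_coefficients(net).values())
        assert all(b == 0.0 for b in betweenness(net).values())
        pset = make_set({"K0", "K1"})
        assert gspd(net, pset)[1] == 1.0
        assert cspd(net, pset)[1] == 1.0


class TestHubs:
    def test_cutoff_5(self):
        assert classify_hubs([1, 6, 13], 5) == (2, pytest.approx(2 / 3))

    def test_cutoff_12(self):
        assert classify_hubs([1, 6, 13], 12) == (1, pytest.approx(1 / 3))

    def test_cutoff_0_all_hubs(self):
        count, frac = classify_hubs([1, 2, 3], 0)
        assert (count, frac) == (3, 1.0)

    def test_strictness(self):
        assert classify_hubs([5, 5, 6], 5) == (1, pytest.approx(1 / 3))

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            classify_hubs([], 5)


class TestBuildProfile:
    def test_triangle_full_set_gspd_undefined(self):
        net = make_net(TRIANGLE)
        prof = build_profile(net, make_set({"A", "B", "C"}))
        avgs = prof.averages()
        assert math.isnan(avgs["gSPD"])
        assert avgs["k"] == 2.0
        assert avgs["C"] == 1.0
        assert avgs["cSPD"] == 1.0

    def test_k4_two_node_set_hand_values(self):
        net = make_net(list(itertools.combinations("ABCD", 2)))
        prof = build_profile(net, make_set({"A", "B"}))
        avgs = prof.averages()
        assert avgs == {"k": 3.0, "B": 0.0, "C": 1.0, "gSPD": 1.0, "cSPD": 1.0}

    def test_averages_equal_recomputation(self, small_world):
        net = small_world.net
        pset = small_world.sets["cancer"]
        prof = build_profile(net, pset)
        # independent recomputation from raw per-node maps
        deg = degrees(net)
        B = betweenness(net)
        C = clustering_coefficients(net)
        g_per, _ = gspd(net, pset)
        c_per, _ = cspd(net, pset)
        members = sorted(pset.mapped)
        avgs = prof.averages()
        assert avgs["k"] == pytest.approx(np.mean([deg[v] for v in members]))
        assert avgs["B"] == pytest.approx(np.mean([B[v] for v in members]))
        assert avgs["C"] == pytest.approx(
            np.nanmean([C[v] for v in members])
        )
        assert avgs["gSPD"] == pytest.approx(np.nanmean([g_per[v] for v in members]))
        assert avgs["cSPD"] == pytest.approx(np.nanmean([c_per[v] for v in members]))

    def test_empty_set_errors(self, small_world):
        empty = make_set(set())
        with pytest.raises(ValueError):
            build_profile(small_world.net, empty)
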