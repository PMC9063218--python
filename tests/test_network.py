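"""Epistatic network construction and permutation topology tests.

The enumeration oracle walks every possible edge set of the null model
(all subsets of m distinct vertex pairs), independent of the sampler it
checks.
"""

import itertools
import math

import numpy as np
import pytest

from epinet.network import (EpistaticNetwork, build_network,
                            connectivity_pvalue, find_hubs, is_connected,
                            max_degree_pvalue, topology_report)


def _enumerate_pvalues(n, m):
    """Exact connectivity and max-degree>=d probabilities by enumeration."""
    pairs = list(itertools.combinations(range(n), 2))
    conn = 0
    degree_tail = {}
    total = 0
    for edges in itertools.combinations(pairs, m):
        total += 1
        deg = {}
        parent = {}

        def find(v):
            while parent[v] != v:
                parent[v] = parent[parent[v]]
                v = parent[v]
            return v

        comps = 0
        for a, b in edges:
            deg[a] = deg.get(a, 0) + 1
            deg[b] = deg.get(b, 0) + 1
            for v in (a, b):
                if v not in parent:
                    parent[v] = v
                    comps += 1
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
                comps -= 1
        if comps == 1:
            conn += 1
        dmax = max(deg.values())
        degree_tail[dmax] = degree_tail.get(dmax, 0) + 1
    p_conn = conn / total
    tail = {}
    acc = 0
    for d in sorted(degree_tail, reverse=True):
        acc += degree_tail[d]
        tail[d] = acc / total
    return p_conn, tail


class TestBuildNetwork:
    def test_single_edge(self):
        net = build_network([("a", "b")], {"a", "b", "c"})
        assert net.m == 1 and len(net.vertices) == 3

    def test_duplicate_edges_deduplicated(self):
        net = build_network([("a", "b"), ("b", "a")], {"a", "b"})
        assert net.m == 1

    def test_union_counts_shared_edge_once(self):
        p = EpistaticNetwork("M", "physical", {"a", "b", "c"},
                            {("a", "b"), ("b", "c")})
        e = EpistaticNetwork("M", "eqtl", {"b", "c", "d"},
                            {("b", "c"), ("c", "d")})
        j = p.union(e)
        assert j.provenance == "joint"
        assert j.m == 3
        assert j.vertices == {"a", "b", "c", "d"}
        assert j.edges >= p.edges and j.edges >= e.edges

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError):
            build_network([("a", "a")], {"a"})


class TestIsConnected:
    def test_single_edge_connected(self):
        assert is_connected(build_network([("a", "b")], {"a", "b", "z"}))

    def test_two_disjoint_edges_not_connected(self):
        assert not is_connected(
            build_network([("a", "b"), ("c", "d")], set("abcd")))

    def test_path_of_three_edges_connected(self):
        assert is_connected(
            build_network([("a", "b"), ("b", "c"), ("c", "d")], set("abcd")))

    def test_edgeless_undefined(self):
        with pytest.raises(ValueError):
            is_connected(build_network([], {"a", "b"}))


class TestConnectivityPvalue:
    @pytest.mark.parametrize("seed", [0, 1, 99])
    @pytest.mark.parametrize("S", [1, 37, 1000])
    def test_single_edge_always_one(self, seed, S):
        assert connectivity_pvalue(10, 1, S=S, seed=seed) == 1.0

    def test_complete_graph_always_one(self):
        n = 5
        assert connectivity_pvalue(n, math.comb(n, 2), S=50, seed=0) == 1.0

    def test_two_edges_match_enumeration(self):
        # n=10, m=2: two edges connect iff they share a vertex;
        # enumeration gives 360/990
        exact, _ = _enumerate_pvalues(10, 2)
        assert exact == pytest.approx(360 / 990)
        S = 4000
        got = connectivity_pvalue(10, 2, S=S, seed=5)
        assert abs(got - exact) < 3 * math.sqrt(exact * (1 - exact) / S)

    @pytest.mark.parametrize("n,m", [(5, 2), (6, 3), (8, 4)])
    def test_matches_enumeration_within_monte_carlo_error(self, n, m):
        exact, _ = _enumerate_pvalues(n, m)
        S = 3000
        got = connectivity_pvalue(n, m, S=S, seed=17)
        assert abs(got - exact) < 3 * math.sqrt(exact * (1 - exact) / S) + 1e-12

    def test_m_out_of_range(self):
        with pytest.raises(ValueError):
            connectivity_pvalue(4, 7, S=10, seed=0)


class TestMaxDegreePvalue:
    def test_degree_one_always_reached(self):
        assert max_degree_pvalue(12, 3, 1, S=100, seed=0) == 1.0

    def test_degree_cannot_exceed_edge_count(self):
        assert max_degree_pvalue(12, 2, 3, S=500, seed=0) == 0.0

    def test_two_edges_degree_two_equals_connectivity_case(self):
        exact, tail = _enumerate_pvalues(10, 2)
        assert tail[2] == pytest.approx(exact)  # share-a-vertex events coincide
        S = 4000
        got = max_degree_pvalue(10, 2, 2, S=S, seed=3)
        assert abs(got - exact) < 3 * math.sqrt(exact * (1 - exact) / S)

    @pytest.mark.parametrize("n,m,d", [(6, 3, 2), (8, 4, 2), (8, 4, 3)])
    def test_matches_enumeration_within_monte_carlo_error(self, n, m, d):
        _, tail = _enumerate_pvalues(n, m)
        exact = tail.get(d, 0.0)
        S = 3000
        got = max_degree_pvalue(n, m, d, S=S, seed=29)
        assert abs(got - exact) < 3 * math.sqrt(exact * (1 - exact) / S) + 1e-12

    def test_monotone_in_observed_degree(self):
        ps = [max_degree_pvalue(8, 4, d, S=2000, seed=7) for d in (1, 2, 3, 4)]
        assert ps == sorted(ps, reverse=True)


class TestFindHubs:
    def test_star_center_is_hub(self):
        edges = [("hub", f"v{i}") for i in range(5)]
        net = build_network(edges, {f"v{i}" for i in range(29)} | {"hub"})
        net.n = 30
        assert find_hubs(net, S=2000, seed=0) == ["hub"]

    def test_single_edge_has_no_hub(self):
        net = build_network([("a", "b")], {"a", "b", "c"})
        net.n = 10
        assert find_hubs(net, S=500, seed=0) == []

    def test_tied_max_degree_vertices_both_returned(self):
        # two centers of degree 4 in a sparse universe
        edges = [("a", "x1"), ("a", "x2"), ("a", "x3"), ("a", "b"),
                 ("b", "y1"), ("b", "y2"), ("b", "y3")]
        net = build_network(edges, set("ab")
                            | {"x1", "x2", "x3", "y1", "y2", "y3"}
                            | {f"z{i}" for i in range(22)})
        net.n = 30
        hubs = find_hubs(net, S=2000, seed=1)
        assert hubs == ["a", "b"]


def test_topology_report_columns(small_bundle):
    nets = [
        build_network([("G01", "G02")], set(small_bundle.gene_ids),
                      map_id="SYN1", provenance="physical"),
        build_network([("G01", "G02"), ("G02", "G03")],
                      set(small_bundle.gene_ids), map_id="SYN1",
                      provenance="eqtl"),
    ]
    df = topology_report(nets, S=200, seed=0)
    assert list(df["m"]) == [1, 2]
    assert df.loc[0, "p_conn"] == 1.0
    assert set(df.columns) >= {"map", "provenance", "n", "m", "connected",
                               "p_conn", "d_max", "p_degree", "hubs"}
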