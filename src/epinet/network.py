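"""Epistatic networks and permutation tests of their topology.

The selected gene pairs of a disease map form a network whose vertices are
genes and whose edges are epistatic interactions.  Whether such a network's
shape is surprising is judged by vertex-pair permutation: sample S random
networks of the same number of edges m over the same n vertices, and report
the fraction S'/S of samples that match or exceed the observed property —
forming a single connected component, or reaching the observed maximum
degree.  Connectivity is judged on the subgraph induced by the edges, so a
single-edge network is connected with p-value exactly 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Edge = tuple[str, str]


@dataclass
class EpistaticNetwork:
    """Selected epistatic edges of one disease map and mapping provenance.

    ``n`` is the size of the vertex universe used for permutation (map genes
    with at least one mapped SNP); isolated universe vertices carry no edges
    but do enter the null model.
    """

    map_id: str
    provenance: str  # "physical" | "eqtl" | "joint"
    vertices: set[str]
    edges: set[Edge]
    n: int = 0

    def __post_init__(self) -> None:
        canon = set()
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            canon.add((a, b) if a < b else (b, a))
        if len(canon) < len(self.edges):
            logger.warning("duplicate edges deduplicated")
        self.edges = canon
        used = {v for e in self.edges for v in e}
        if not used <= self.vertices:
            raise ValueError("edges reference vertices outside the universe")
        if self.n <= 0:
            self.n = len(self.vertices)

    @property
    def m(self) -> int:
        return len(self.edges)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.vertices)
        g.add_edges_from(self.edges)
        return g

    def max_degree(self) -> int:
        if not self.edges:
            return 0
        return max(d for _, d in self.graph().degree)

    def union(self, other: "EpistaticNetwork") -> "EpistaticNetwork":
        """Joint network: union of edge sets and of vertex universes."""
        if self.map_id != other.map_id:
            raise ValueError("joint network requires networks of the same map")
        return EpistaticNetwork(
            map_id=self.map_id,
            provenance="joint",
            vertices=self.vertices | other.vertices,
            edges=self.edges | other.edges,
            n=len(self.vertices | other.vertices),
        )


def build_network(edge_list: list[Edge], vertex_universe: set[str],
                  map_id: str = "", provenance: str = "physical") -> EpistaticNetwork:
    """Assemble a network from an edge list over a vertex universe."""
    return EpistaticNetwork(map_id=map_id, provenance=provenance,
                            vertices=set(vertex_universe), edges=set(edge_list))


def is_connected(network: EpistaticNetwork) -> bool:
    """Whether the edge-induced subgraph forms a single connected component.

    Isolated universe vertices are ignored; undefined for edgeless networks.
    """
    if network.m == 0:
        raise ValueError("connectivity undefined for a network without edges")
    sub = network.graph().edge_subgraph(network.edges)
    return nx.is_connected(sub)


def _sample_edge_indices(n: int, m: int, S: int, rng: np.random.Generator):
    """S draws of m distinct vertex pairs among the C(n,2) possible, encoded
    as flat pair indices."""
    n_pairs = math.comb(n, 2)
    for _ in range(S):
        yield rng.choice(n_pairs, size=m, replace=False)


_PAIR_CACHE: dict[int, np.ndarray] = {}


def _pair_table(n: int) -> np.ndarray:
    """(C(n,2), 2) array decoding flat pair index -> (i, j)."""
    if n not in _PAIR_CACHE:
        iu = np.triu_indices(n, k=1)
        _PAIR_CACHE[n] = np.column_stack(iu)
    return _PAIR_CACHE[n]


def _edges_connected(pairs: np.ndarray) -> bool:
    """Union-find connectivity of the edge-induced subgraph."""
    parent: dict[int, int] = {}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    comps = 0
    for i, j in pairs:
        for v in (int(i), int(j)):
            if v not in parent:
                parent[v] = v
                comps += 1
        ri, rj = find(int(i)), find(int(j))
        if ri != rj:
            parent[ri] = rj
            comps -= 1
    return comps == 1


def connectivity_pvalue(n: int, m: int, S: int = 1000, seed: int = 0) -> float:
    """Permutation p-value for the network forming one connected component.

    Samples S networks of m distinct vertex pairs over n vertices and
    reports the fraction whose edge-induced subgraph is connected (no
    pseudo-count; a never-connected draw reports 0.0).  m = 1 gives exactly
    1.0 for any seed.
    """
    _check_nm(n, m)
    if S < 1:
        raise ValueError("S must be >= 1")
    rng = np.random.default_rng(seed)
    table = _pair_table(n)
    hits = sum(
        _edges_connected(table[idx]) for idx in _sample_edge_indices(n, m, S, rng)
    )
    return hits / S


def max_degree_pvalue(n: int, m: int, d_obs: int, S: int = 1000,
                      seed: int = 0) -> float:
    """Permutation p-value for containing a vertex of degree >= d_obs."""
    _check_nm(n, m)
    if d_obs < 1:
        raise ValueError("observed degree must be >= 1")
    if S < 1:
        raise ValueError("S must be >= 1")
    rng = np.random.default_rng(seed)
    table = _pair_table(n)
    hits = 0
    for idx in _sample_edge_indices(n, m, S, rng):
        pairs = table[idx]
        counts = np.bincount(pairs.ravel(), minlength=n)
        if counts.max() >= d_obs:
            hits += 1
    return hits / S


def _check_nm(n: int, m: int) -> None:
    if n < 2:
        raise ValueError("need at least two vertices")
    if not (1 <= m <= math.comb(n, 2)):
        raise ValueError(f"m={m} outside [1, C({n},2)={math.comb(n, 2)}]")


def find_hubs(network: EpistaticNetwork, S: int = 1000, seed: int = 0,
              alpha: float = 0.05) -> list[str]:
    """Vertices of maximum degree, when that degree is significant.

    A hub is a node of degree greater than expected by chance: if the
    permutation p-value of the observed maximum degree is below ``alpha``,
    all vertices tied at the maximum are returned, else none.
    """
    if network.m == 0:
        return []
    d_max = network.max_degree()
    if d_max < 1:
        return []
    p = max_degree_pvalue(network.n, network.m, d_max, S=S, seed=seed)
    if p >= alpha:
        return []
    deg = dict(network.graph().degree)
    return sorted(v for v, d in deg.items() if d == d_max)


def topology_report(networks: list[EpistaticNetwork], S: int = 1000,
                    seed: int = 0, alpha: float = 0.05) -> pd.DataFrame:
    """Connectivity and hub permutation summary, one row per network."""
    rows = []
    for k, net in enumerate(networks):
        if net.m == 0:
            rows.append({"map": net.map_id, "provenance": net.provenance,
                         "n": net.n, "m": 0, "connected": None,
                         "p_conn": np.nan, "d_max": 0, "p_degree": np.nan,
                         "hubs": ""})
            continue
        d_max = net.max_degree()
        rows.append({
            "map": net.map_id,
            "provenance": net.provenance,
            "n": net.n,
            "m": net.m,
            "connected": is_connected(net),
            "p_conn": connectivity_pvalue(net.n, net.m, S=S, seed=seed + 2 * k),
            "d_max": d_max,
            "p_degree": max_degree_pvalue(net.n, net.m, d_max, S=S,
                                          seed=seed + 2 * k + 1),
            "hubs": ",".join(find_hubs(net, S=S, seed=seed + 2 * k + 1,
                                       alpha=alpha)),
        })
    return pd.DataFrame(rows)
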