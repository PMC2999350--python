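"""Per-node and per-set topological measures.

Measures: degree k and its distribution P(k); clustering coefficient C
(defined only for k >= 2); unweighted shortest-path betweenness B
(pair-dependency accumulation by default, with a literal raw path-count
variant); per-set mean distances to nodes outside the set (gSPD) and to
other set members (cSPD); and hub classification at a degree cutoff.

Undefined values are represented as NaN and excluded from set averages.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .interactome import Interactome, ProteinSet

logger = logging.getLogger(__name__)

MEASURES = ("k", "B", "C", "gSPD", "cSPD")

__all__ = [
    "MEASURES",
    "TopologyProfile",
    "degrees",
    "mean_degree",
    "degree_distribution",
    "clustering_coefficients",
    "betweenness",
    "shortest_path_lengths",
    "gspd",
    "cspd",
    "classify_hubs",
    "build_profile",
]


def degrees(net: Interactome) -> dict[str, int]:
    """Degree of every node (neighbor count in a simple graph)."""
    if net.n_nodes == 0:
        raise ValueError("empty network")
    return dict(net.graph.degree())


def mean_degree(arg: Interactome | Iterable[int]) -> float:
    """Arithmetic mean degree of a network (2m/n) or of given degree values."""
    if isinstance(arg, Interactome):
        if arg.n_nodes == 0:
            raise ValueError("empty network")
        return 2.0 * arg.n_edges / arg.n_nodes
    values = list(arg)
    if not values:
        raise ValueError("empty degree sample")
    return float(np.mean(values))


def degree_distribution(deg_values: Iterable[int]) -> dict[int, float]:
    """Empirical P(k): probability that a node has exactly k links."""
    values = list(deg_values)
    if not values:
        raise ValueError("empty degree sample")
    n = len(values)
    counts: dict[int, int] = {}
    for k in values:
        counts[k] = counts.get(k, 0) + 1
    return {k: c / n for k, c in sorted(counts.items())}


def clustering_coefficients(net: Interactome) -> dict[str, float]:
    """C(v) = 2 t(v) / (k(v) (k(v)-1)) for k >= 2, NaN otherwise.

    t(v) is the number of edges among v's neighbors.
    """
    deg = net.graph.degree()
    raw = nx.clustering(net.graph)
    return {v: (raw[v] if deg[v] >= 2 else math.nan) for v in net.graph.nodes}


def betweenness(net: Interactome, variant: str = "pair-dependency") -> dict[str, float]:
    """Unweighted shortest-path betweenness of every node.

    ``pair-dependency`` (default) accumulates sigma_st(v)/sigma_st over
    unordered pairs s<t with endpoints excluded (Brandes, unnormalized).
    ``raw-count`` counts the shortest paths themselves: the number of
    shortest paths between all pairs of other nodes that traverse v.
    The raw count is O(n^3) and intended for subnetwork-sized graphs.
    """
    if variant == "pair-dependency":
        return dict(nx.betweenness_centrality(net.graph, normalized=False))
    if variant == "raw-count":
        return _raw_count_betweenness(net.graph)
    raise ValueError(f"unknown betweenness variant: {variant!r}")


def _raw_count_betweenness(g: nx.Graph) -> dict[str, float]:
    nodes = sorted(g.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    dist = np.full((n, n), np.inf)
    sigma = np.zeros((n, n))
    for s in nodes:
        i = idx[s]
        d, sg = _bfs_sigma(g, s)
        for v, dv in d.items():
            dist[i, idx[v]] = dv
            sigma[i, idx[v]] = sg[v]
    out: dict[str, float] = {}
    for v in nodes:
        j = idx[v]
        # sigma_st(v) = sigma(s,v) * sigma(v,t) when d(s,v)+d(v,t) == d(s,t)
        through = dist[:, j][:, None] + dist[j, :][None, :]
        on_path = np.isfinite(through) & (through == dist)
        counts = sigma[:, j][:, None] * sigma[j, :][None, :]
        counts[~on_path] = 0.0
        counts[j, :] = 0.0
        counts[:, j] = 0.0
        np.fill_diagonal(counts, 0.0)
        out[v] = float(counts.sum() / 2.0)  # each unordered pair counted once
    return out


def _bfs_sigma(g: nx.Graph, source) -> tuple[dict, dict]:
    """BFS distances and shortest-path counts from one source."""
    dist = {source: 0}
    sigma = {source: 1.0}
    queue = [source]
    while queue:
        nxt = []
        for u in queue:
            du = dist[u]
            for w in g.adj[u]:
                if w not in dist:
                    dist[w] = du + 1
                    sigma[w] = sigma[u]
                    nxt.append(w)
                elif dist[w] == du + 1:
                    sigma[w] += sigma[u]
        queue = nxt
    return dist, sigma


def shortest_path_lengths(net: Interactome, source: str) -> dict[str, int]:
    """BFS distances from ``source``; unreachable nodes are absent."""
    if source not in net.graph:
        raise ValueError(f"source {source!r} not in network")
    return dict(nx.single_source_shortest_path_length(net.graph, source))


def gspd(net: Interactome, pset: ProteinSet) -> tuple[dict[str, float], float]:
    """Mean distance from each set member to reachable nodes outside the set.

    Returns per-node values (NaN where no outside node is reachable) and
    the set average over defined values.
    """
    members = set(pset.mapped)
    if not members:
        raise ValueError(f"set {pset.name!r} has no mapped members")
    if not (net.nodes - members):
        raise ValueError("set covers network: no outside nodes for gSPD")
    per_node: dict[str, float] = {}
    for v in members:
        dists = nx.single_source_shortest_path_length(net.graph, v)
        vals = [d for u, d in dists.items() if u not in members]
        per_node[v] = float(np.mean(vals)) if vals else math.nan
    return per_node, _nanmean(per_node.values())


def cspd(net: Interactome, pset: ProteinSet) -> tuple[dict[str, float], float]:
    """Mean distance from each set member to other reachable set members."""
    members = set(pset.mapped)
    if len(members) < 2:
        raise ValueError(f"set {pset.name!r} needs >=2 mapped members for cSPD")
    per_node: dict[str, float] = {}
    for v in members:
        dists = nx.single_source_shortest_path_length(net.graph, v)
        vals = [d for u, d in dists.items() if u in members and u != v]
        per_node[v] = float(np.mean(vals)) if vals else math.nan
    return per_node, _nanmean(per_node.values())


def classify_hubs(deg_values: Iterable[int], cutoff: int) -> tuple[int, float]:
    """Count and fraction of nodes with degree strictly greater than cutoff."""
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    values = list(deg_values)
    if not values:
        raise ValueError("empty degree sample")
    n_hub = sum(1 for k in values if k > cutoff)
    return n_hub, n_hub / len(values)


def _nanmean(values: Iterable[float]) -> float:
    arr = np.asarray(list(values), dtype=float)
    defined = arr[~np.isnan(arr)]
    return float(defined.mean()) if defined.size else math.nan


@dataclass
class TopologyProfile:
    """Per-node topology table for one protein set, plus set averages.

    ``table`` is indexed by node with columns k, B, C, gSPD, cSPD;
    undefined entries are NaN and excluded from averages.
    """

    set_name: str
    table: pd.DataFrame
    n_genes: int | None = None

    def averages(self) -> dict[str, float]:
        """Arithmetic mean of each measure over nodes with defined values."""
        return {m: _nanmean(self.table[m].to_numpy()) for m in MEASURES}

    def values(self, measure: str) -> np.ndarray:
        """Defined per-node values of one measure (NaN dropped)."""
        if measure not in MEASURES:
            raise ValueError(f"unknown measure: {measure!r}")
        col = self.table[measure].to_numpy(dtype=float)
        return col[~np.isnan(col)]

    def hub_stats(self, cutoff: int) -> tuple[int, float]:
        return classify_hubs(self.table["k"].astype(int).tolist(), cutoff)

    def summary_row(self, hub_cutoffs: Iterable[int] = ()) -> dict:
        """One flat row in the shape of the set-summary table."""
        row: dict = {
            "set": self.set_name,
            "n_genes": self.n_genes if self.n_genes is not None else len(self.table),
            "n_mapped": len(self.table),
        }
        row.update(self.averages())
        for cutoff in hub_cutoffs:
            count, frac = self.hub_stats(cutoff)
            row[f"hubs_gt{cutoff}"] = count
            row[f"hub_frac_gt{cutoff}"] = frac
        return row


def build_profile(
    net: Interactome,
    pset: ProteinSet,
    betweenness_variant: str = "pair-dependency",
    *,
    precomputed_B: Mapping[str, float] | None = None,
    precomputed_C: Mapping[str, float] | None = None,
) -> TopologyProfile:
    """Assemble all per-node measures for one set.

    Whole-network betweenness and clustering may be passed in to avoid
    recomputation when profiling several sets on the same network.
    """
    members = sorted(pset.mapped)
    if not members:
        raise ValueError(f"set {pset.name!r} has no mapped members")
    B = precomputed_B if precomputed_B is not None else betweenness(net, betweenness_variant)
    C = precomputed_C if precomputed_C is not None else clustering_coefficients(net)
    deg = net.graph.degree()

    if net.nodes - set(members):
        g_per, _ = gspd(net, pset)
    else:
        g_per = {v: math.nan for v in members}
    if len(members) >= 2:
        c_per, _ = cspd(net, pset)
    else:
        c_per = {v: math.nan for v in members}

    table = pd.DataFrame(
        {
            "k": [deg[v] for v in members],
            "B": [B[v] for v in members],
            "C": [C[v] for v in members],
            "gSPD": [g_per[v] for v in members],
            "cSPD": [c_per[v] for v in members],
        },
        index=pd.Index(members, name="node"),
    )
    return TopologyProfile(set_name=pset.name, table=table, n_genes=len(pset.genes))
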