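"""Set-specific subnetworks, Erdos-Renyi G(n,m) nulls and centralization.

The randomization test draws G(n,m) replicates matching the observed
subnetwork's node and edge counts, summarizes each replicate by its mean
betweenness B, mean clustering coefficient C (over nodes with k >= 2)
and mean shortest-path distance L (over reachable unordered pairs), and
reports empirical p-values n_B/R, n_C/R, n_L/R from strict-inequality
exceedance counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .interactome import Interactome, ProteinSet

__all__ = [
    "Subnetwork",
    "NullSummaries",
    "NullModelResult",
    "CentralizationReport",
    "induced_subnetwork",
    "er_gnm",
    "null_summaries",
    "null_distribution",
    "randomization_test",
    "degree_centralization",
    "removal_effect",
]


@dataclass
class Subnetwork:
    """Graph induced on a protein set using only within-set edges."""

    set_name: str
    graph: nx.Graph
    components: list[set[str]]
    n_linked: int

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def linked_graph(self) -> nx.Graph:
        """Subgraph restricted to members with at least one within-set edge."""
        linked = [v for v in self.graph.nodes if self.graph.degree[v] >= 1]
        return self.graph.subgraph(linked).copy()


class NullSummaries(NamedTuple):
    B: float
    C: float
    L: float


def induced_subnetwork(net: Interactome, pset: ProteinSet) -> Subnetwork:
    """Extract the subgraph over a set's mapped members."""
    sub = net.graph.subgraph(pset.mapped).copy()
    components = [set(c) for c in nx.connected_components(sub) if len(c) > 1]
    components.sort(key=lambda c: (-len(c), min(c)))
    n_linked = sum(1 for v in sub.nodes if sub.degree[v] >= 1)
    return Subnetwork(set_name=pset.name, graph=sub, components=components, n_linked=n_linked)


def er_gnm(n: int, m: int, seed) -> nx.Graph:
    """Erdos-Renyi G(n,m): exactly m edges uniform among unordered pairs.

    ``seed`` may be an int or a numpy Generator (consumed, enabling
    streams of replicates).
    """
    max_m = n * (n - 1) // 2
    if not (0 <= m <= max_m):
        raise ValueError(f"m={m} out of range [0, {max_m}] for n={n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return nx.gnm_random_graph(n, m, seed=rng)


def _mean_pairwise_distance(g: nx.Graph) -> float:
    """Mean shortest-path distance over reachable unordered pairs."""
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("no node pairs")
    adj = nx.to_scipy_sparse_array(g, format="csr")
    dmat = _csgraph_shortest_path(adj, method="D", unweighted=True)
    finite = np.isfinite(dmat) & (dmat > 0)
    if not finite.any():
        raise ValueError("no reachable pairs: L undefined")
    return float(dmat[finite].mean())  # each unordered pair appears twice; mean unaffected


def null_summaries(g: nx.Graph, measures: Sequence[str] = ("B", "C", "L")) -> NullSummaries:
    """Mean betweenness, clustering (k>=2 nodes) and pairwise distance.

    Measures not requested are returned as NaN, which lets callers skip
    the costly betweenness pass when only C and L are needed.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    B = C = L = math.nan
    if "B" in measures:
        bc = nx.betweenness_centrality(g, normalized=False)
        B = float(np.mean(list(bc.values())))
    if "C" in measures:
        deg = g.degree()
        cl = nx.clustering(g)
        vals = [cl[v] for v in g.nodes if deg[v] >= 2]
        C = float(np.mean(vals)) if vals else math.nan
    if "L" in measures:
        L = _mean_pairwise_distance(g)
    return NullSummaries(B=B, C=C, L=L)


def null_distribution(
    n: int, m: int, reps: int, seed, measures: Sequence[str] = ("B", "C", "L")
) -> dict[str, np.ndarray]:
    """Replicate summary arrays over ``reps`` seeded G(n,m) draws."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: dict[str, list[float]] = {meas: [] for meas in measures}
    for _ in range(reps):
        g = er_gnm(n, m, rng)
        summ = null_summaries(g, measures)
        for meas in measures:
            out[meas].append(getattr(summ, meas))
    return {meas: np.asarray(vals) for meas, vals in out.items()}


@dataclass
class NullModelResult:
    n_nodes: int
    n_edges: int
    reps: int
    observed_B: float
    observed_C: float
    observed_L: float
    null_mean_B: float
    null_mean_C: float
    null_mean_L: float
    null_sd_B: float
    null_sd_C: float
    null_sd_L: float
    n_B: int
    n_C: int
    n_L: int
    p_B: float
    p_C: float
    p_L: float
    seed: int | None = None

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def randomization_test(
    observed: NullSummaries | tuple[float, float, float],
    n: int,
    m: int,
    reps: int = 1000,
    seed: int | None = 0,
) -> NullModelResult:
    """Empirical p-values of observed subnetwork summaries against G(n,m).

    n_B counts replicates whose mean betweenness is strictly higher than
    observed, n_C likewise for clustering, and n_L counts replicates
    whose mean distance is strictly shorter; ties count as non-exceeding.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    obs = NullSummaries(*observed)
    dists = null_distribution(n, m, reps, seed)
    n_B = int(np.sum(dists["B"] > obs.B))
    n_C = int(np.sum(dists["C"] > obs.C))
    n_L = int(np.sum(dists["L"] < obs.L))
    return NullModelResult(
        n_nodes=n, n_edges=m, reps=reps,
        observed_B=float(obs.B), observed_C=float(obs.C), observed_L=float(obs.L),
        null_mean_B=float(dists["B"].mean()),
        null_mean_C=float(dists["C"].mean()),
        null_mean_L=float(dists["L"].mean()),
        null_sd_B=float(dists["B"].std(ddof=1)) if reps > 1 else 0.0,
        null_sd_C=float(dists["C"].std(ddof=1)) if reps > 1 else 0.0,
        null_sd_L=float(dists["L"].std(ddof=1)) if reps > 1 else 0.0,
        n_B=n_B, n_C=n_C, n_L=n_L,
        p_B=n_B / reps, p_C=n_C / reps, p_L=n_L / reps,
        seed=seed if isinstance(seed, int) else None,
    )


def degree_centralization(g: nx.Graph) -> float:
    """Freeman degree centralization: sum(k_max - k_v) / ((n-1)(n-2)).

    1 for the star, 0 for any regular graph.
    """
    n = g.number_of_nodes()
    if n < 3:
        raise ValueError("centralization needs >= 3 nodes")
    degs = np.array([d for _, d in g.degree()], dtype=float)
    return float((degs.max() - degs).sum() / ((n - 1) * (n - 2)))


@dataclass
class CentralizationReport:
    before: float
    after: float
    removed: list[str]

    def __post_init__(self):
        for val in (self.before, self.after):
            if not (0.0 <= val <= 1.0):
                raise ValueError("centralization out of [0,1]")


def removal_effect(g: nx.Graph, nodes_to_remove: Iterable[str]) -> CentralizationReport:
    """Degree centralization before and after deleting the given nodes."""
    removed = list(nodes_to_remove)
    missing = [v for v in removed if v not in g]
    if missing:
        raise ValueError(f"nodes not in graph: {missing}")
    if g.number_of_nodes() - len(removed) < 3:
        raise ValueError("removal leaves fewer than 3 nodes")
    before = degree_centralization(g)
    h = g.copy()
    h.remove_nodes_from(removed)
    after = degree_centralization(h)
    return CentralizationReport(before=before, after=after, removed=removed)
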