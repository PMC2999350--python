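"""Independent brute-force reference implementations used only by tests.

Everything here is deliberately naive (explicit enumeration, double
loops, Floyd-Warshall) and shares no code with the package under test.
"""

from __future__ import annotations

import itertools
import math
from math import comb


def adjacency(nodes, edges):
    adj = {v: set() for v in nodes}
    for a, b in edges:
        if a != b:
            adj[a].add(b)
            adj[b].add(a)
    return adj


def bf_degrees(nodes, edges):
    adj = adjacency(nodes, edges)
    return {v: len(adj[v]) for v in nodes}


def bf_clustering(nodes, edges):
    """C by enumerating neighbor pairs; NaN for degree < 2."""
    adj = adjacency(nodes, edges)
    out = {}
    for v in nodes:
        nbrs = sorted(adj[v])
        k = len(nbrs)
        if k < 2:
            out[v] = math.nan
            continue
        links = sum(1 for a, b in itertools.combinations(nbrs, 2) if b in adj[a])
        out[v] = 2.0 * links / (k * (k - 1))
    return out


def bf_all_pairs(nodes, edges):
    """Floyd-Warshall distances; missing key means unreachable."""
    nodes = list(nodes)
    dist = {u: {v: (0 if u == v else math.inf) for v in nodes} for u in nodes}
    for a, b in edges:
        if a != b:
            dist[a][b] = dist[b][a] = 1
    for w in nodes:
        for u in nodes:
            duw = dist[u][w]
            if duw == math.inf:
                continue
            for v in nodes:
                alt = duw + dist[w][v]
                if alt < dist[u][v]:
                    dist[u][v] = alt
    return {
        u: {v: int(d) for v, d in row.items() if d < math.inf}
        for u, row in dist.items()
    }


def _all_shortest_paths(adj, dist_from_s, s, t):
    """All shortest s-t paths by backward walking over BFS levels."""
    if t not in dist_from_s:
        return []
    paths = []

    def walk(v, suffix):
        if v == s:
            paths.append([s] + suffix)
            return
        for u in adj[v]:
            if u in dist_from_s and dist_from_s[u] == dist_from_s[v] - 1:
                walk(u, [v] + suffix)

    walk(t, [])
    return paths


def bf_betweenness(nodes, edges, variant="pair-dependency"):
    """Betweenness by explicit enumeration of every shortest path."""
    adj = adjacency(nodes, edges)
    dists = bf_all_pairs(nodes, edges)
    B = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(sorted(nodes), 2):
        paths = _all_shortest_paths(adj, dists[s], s, t)
        if not paths:
            continue
        through = {}
        for path in paths:
            for v in path[1:-1]:
                through[v] = through.get(v, 0) + 1
        for v, cnt in through.items():
            B[v] += cnt / len(paths) if variant == "pair-dependency" else cnt
    return B


def bf_gspd(nodes, edges, members):
    dists = bf_all_pairs(nodes, edges)
    members = set(members)
    out = {}
    for v in members:
        vals = [d for u, d in dists[v].items() if u not in members]
        out[v] = sum(vals) / len(vals) if vals else math.nan
    return out


def bf_cspd(nodes, edges, members):
    dists = bf_all_pairs(nodes, edges)
    members = set(members)
    out = {}
    for v in members:
        vals = [d for u, d in dists[v].items() if u in members and u != v]
        out[v] = sum(vals) / len(vals) if vals else math.nan
    return out


def bf_pair_distance_sum(nodes, edges):
    """Sum of d(s,t) - 1 over reachable unordered pairs."""
    dists = bf_all_pairs(nodes, edges)
    total = 0
    for s, t in itertools.combinations(sorted(nodes), 2):
        if t in dists[s]:
            total += dists[s][t] - 1
    return total


def exact_ranksum_pvalue(x, y):
    """Two-sided rank-sum p by enumerating all label assignments."""
    pooled = sorted(x) + sorted(y)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    ranks = {v: i + 1 for i, v in enumerate(sorted(pooled))}
    obs = sum(ranks[v] for v in x)
    nx_ = len(x)
    all_sums = [
        sum(combo)
        for combo in itertools.combinations(sorted(ranks.values()), nx_)
    ]
    mean = (nx_ * (len(pooled) + 1)) / 2
    obs_dev = abs(obs - mean)
    extreme = sum(1 for s in all_sums if abs(s - mean) >= obs_dev - 1e-9)
    return extreme / len(all_sums)


def hypergeom_tail(k, N, K, n):
    """P(X >= k) for X ~ Hypergeometric(N, K, n) from first principles."""
    denom = comb(N, n)
    total = 0
    for i in range(k, min(K, n) + 1):
        total += comb(K, i) * comb(N - K, n - i)
    return total / denom


def bh_adjust(ps):
    """BH step-up computed the slow way (per-index minimum over j >= rank)."""
    n = len(ps)
    order = sorted(range(n), key=lambda i: ps[i])
    adjusted = [None] * n
    running_min = 1.0
    for pos in range(n - 1, -1, -1):
        i = order[pos]
        running_min = min(running_min, ps[i] * n / (pos + 1))
        adjusted[i] = min(running_min, 1.0)
    return adjusted
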