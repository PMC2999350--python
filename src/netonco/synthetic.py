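"""Synthetic worlds with known ground truth.

Generates heavy-tailed interactomes, protein sets planted with a
configurable degree bias (sampling probability proportional to k^alpha,
alpha=0 giving a uniform control-like set), and GMT annotation catalogs
with planted-enriched pathways.  Every generator is driven by a numpy
SeedSequence so a world regenerates bit-for-bit from its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .interactome import Interactome, ProteinSet, write_edge_tsv
from .nullmodel import er_gnm

__all__ = [
    "SyntheticWorld",
    "generate_network",
    "plant_set",
    "plant_catalog",
    "generate_world",
    "write_world",
    "write_gmt",
]

_NODE_FMT = "G{:05d}"


def _relabel(g: nx.Graph) -> nx.Graph:
    mapping = {v: _NODE_FMT.format(i) for i, v in enumerate(sorted(g.nodes))}
    return nx.relabel_nodes(g, mapping)


def _duplication_divergence(
    n: int, p_retain: float, p_anchor: float, rng: np.random.Generator
) -> nx.Graph:
    """Grow by node duplication: copy a random node, keep each of its
    edges with probability p_retain, link to the template with
    probability p_anchor; a duplicate that would end isolated is linked
    to its template so every node participates in an interaction."""
    g = nx.Graph()
    g.add_edge(0, 1)
    for new in range(2, n):
        template = int(rng.integers(new))
        kept = [w for w in g.adj[template] if rng.random() < p_retain]
        g.add_node(new)
        g.add_edges_from((new, w) for w in kept)
        if rng.random() < p_anchor or g.degree[new] == 0:
            g.add_edge(new, template)
    return g


def generate_network(
    n: int,
    model: str = "pa",
    params: Mapping | None = None,
    seed: int | np.random.Generator = 0,
) -> Interactome:
    """Seeded simple undirected graph with gene-symbol-like node names.

    Models: ``pa`` (preferential attachment, param ``m_attach``), ``dd``
    (duplication-divergence, params ``p_retain``, ``p_anchor``) and
    ``er`` (G(n,m), param ``m``).
    """
    if n < 10:
        raise ValueError("need n >= 10 nodes")
    params = dict(params or {})
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if model in ("pa", "preferential_attachment"):
        m_attach = int(params.pop("m_attach", 5))
        if not (1 <= m_attach < n):
            raise ValueError("m_attach must satisfy 1 <= m_attach < n")
        g = nx.barabasi_albert_graph(n, m_attach, seed=rng)
    elif model in ("dd", "duplication_divergence"):
        p_retain = float(params.pop("p_retain", 0.4))
        p_anchor = float(params.pop("p_anchor", 0.1))
        if not (0 <= p_retain <= 1 and 0 <= p_anchor <= 1):
            raise ValueError("p_retain and p_anchor must lie in [0,1]")
        g = _duplication_divergence(n, p_retain, p_anchor, rng)
    elif model == "er":
        m = int(params.pop("m"))
        g = er_gnm(n, m, rng)
    else:
        raise ValueError(f"unknown model: {model!r}")
    if params:
        raise ValueError(f"unused params for model {model!r}: {sorted(params)}")
    g = _relabel(g)
    for _, _, data in g.edges(data=True):
        data["sources"] = {"sim"}
    return Interactome(g)


def _weighted_sample_without_replacement(
    items: Sequence[str], weights: np.ndarray, size: int, rng: np.random.Generator
) -> list[str]:
    """Sequential weighted sampling via the Gumbel top-k trick (exact)."""
    if size > len(items):
        raise ValueError("sample size exceeds population")
    keys = np.log(weights) + rng.gumbel(size=len(items))
    top = np.argpartition(-keys, size - 1)[:size] if size < len(items) else np.arange(len(items))
    return [items[i] for i in top]


def plant_set(
    net: Interactome,
    size: int,
    alpha: float,
    seed: int | np.random.Generator,
    name: str,
    exclude: Iterable[str] = (),
) -> ProteinSet:
    """Sample a protein set with probability proportional to degree^alpha.

    alpha=0 yields a uniform (control-like) set; larger alpha skews the
    set toward hubs.  ``exclude`` removes nodes from the candidate pool
    so disjoint sets can be planted on one network.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pool = sorted(net.nodes - set(exclude))
    if size > len(pool):
        raise ValueError(f"size {size} exceeds available nodes {len(pool)}")
    deg = net.graph.degree()
    weights = np.array([max(deg[v], 1) ** alpha for v in pool], dtype=float)
    members = frozenset(_weighted_sample_without_replacement(pool, weights, size, rng))
    return ProteinSet(name=name, genes=members, mapped=members)


def plant_catalog(
    nodes: Iterable[str],
    n_pathways: int,
    size_range: tuple[int, int],
    enriched_in: ProteinSet | None = None,
    n_enriched: int = 0,
    enrichment_factor: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> tuple[dict[str, tuple[str, frozenset[str]]], dict]:
    """GMT-style catalog with the first ``n_enriched`` pathways oversampling
    members of ``enriched_in`` by ``enrichment_factor``.

    Returns the catalog and a truth record listing the enriched ids.
    """
    pool = sorted(set(nodes))
    lo, hi = size_range
    if not (1 <= lo <= hi <= len(pool)):
        raise ValueError(f"infeasible size range {size_range} for {len(pool)} nodes")
    if not (0 <= n_enriched <= n_pathways):
        raise ValueError("n_enriched must lie in [0, n_pathways]")
    if n_enriched > 0 and enriched_in is None:
        raise ValueError("enriched_in required when n_enriched > 0")
    if enrichment_factor < 1.0:
        raise ValueError("enrichment_factor must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    uniform = np.ones(len(pool))
    biased = uniform
    if enriched_in is not None:
        target = set(enriched_in.mapped)
        biased = np.array([enrichment_factor if v in target else 1.0 for v in pool])
    catalog: dict[str, tuple[str, frozenset[str]]] = {}
    enriched_ids: list[str] = []
    for i in range(n_pathways):
        size = int(rng.integers(lo, hi + 1))
        enriched = i < n_enriched
        weights = biased if enriched else uniform
        members = frozenset(_weighted_sample_without_replacement(pool, weights, size, rng))
        pid = f"PW{i:04d}"
        label = "planted_enriched" if enriched else "background"
        catalog[pid] = (f"{label}_pathway_{i}", members)
        if enriched:
            enriched_ids.append(pid)
    truth = {
        "n_pathways": n_pathways,
        "size_range": [lo, hi],
        "n_enriched": n_enriched,
        "enrichment_factor": enrichment_factor,
        "enriched_ids": enriched_ids,
        "enriched_in": enriched_in.name if enriched_in is not None else None,
    }
    return catalog, truth


@dataclass
class SyntheticWorld:
    """A generated interactome, planted protein sets, catalog and truth."""

    net: Interactome
    sets: dict[str, ProteinSet]
    catalog: dict[str, tuple[str, frozenset[str]]]
    truth: dict = field(default_factory=dict)


def generate_world(
    n: int = 2000,
    model: str = "pa",
    model_params: Mapping | None = None,
    set_specs: Sequence[Mapping] = (
        {"name": "cancer", "size": 200, "alpha": 1.5},
        {"name": "essential", "size": 400, "alpha": 0.8},
    ),
    catalog_spec: Mapping | None = None,
    seed: int = 0,
) -> SyntheticWorld:
    """Full synthetic world from one master seed.

    Sets are planted disjointly in spec order.  ``catalog_spec`` keys:
    n_pathways, size_range, enriched_in (set name), n_enriched,
    enrichment_factor.  The returned truth record is sufficient to
    regenerate the world bit-for-bit.
    """
    ss = np.random.SeedSequence(seed)
    net_seed, sets_seed, cat_seed = ss.spawn(3)
    net = generate_network(n, model, model_params, np.random.default_rng(net_seed))

    sets: dict[str, ProteinSet] = {}
    taken: set[str] = set()
    set_rng = np.random.default_rng(sets_seed)
    for spec in set_specs:
        pset = plant_set(
            net, int(spec["size"]), float(spec.get("alpha", 0.0)),
            set_rng, str(spec["name"]), exclude=taken,
        )
        sets[pset.name] = pset
        taken |= set(pset.mapped)

    catalog: dict[str, tuple[str, frozenset[str]]] = {}
    cat_truth: dict = {}
    if catalog_spec:
        cs = dict(catalog_spec)
        target_name = cs.pop("enriched_in", None)
        target = sets[target_name] if target_name else None
        catalog, cat_truth = plant_catalog(
            net.nodes,
            n_pathways=int(cs.pop("n_pathways", 120)),
            size_range=tuple(cs.pop("size_range", (10, 80))),
            enriched_in=target,
            n_enriched=int(cs.pop("n_enriched", 0)),
            enrichment_factor=float(cs.pop("enrichment_factor", 1.0)),
            seed=np.random.default_rng(cat_seed),
        )
        if cs:
            raise ValueError(f"unknown catalog_spec keys: {sorted(cs)}")

    truth = {
        "seed": seed,
        "n": n,
        "model": model,
        "model_params": dict(model_params or {}),
        "sets": [dict(s) for s in set_specs],
        "catalog": cat_truth,
    }
    return SyntheticWorld(net=net, sets=sets, catalog=catalog, truth=truth)


def write_gmt(catalog: Mapping[str, tuple[str, frozenset[str]]], path: str | Path) -> None:
    lines = [
        "\t".join([pid, catalog[pid][0], *sorted(catalog[pid][1])])
        for pid in sorted(catalog)
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


def write_world(world: SyntheticWorld, outdir: str | Path) -> None:
    """Write network TSV, one file per set, catalog GMT and truth JSON.

    All outputs are sorted so regeneration is byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_edge_tsv(world.net, outdir / "network.tsv")
    for name, pset in world.sets.items():
        (outdir / f"{name}.txt").write_text(
            "\n".join(sorted(pset.genes)) + "\n", encoding="utf-8"
        )
    if world.catalog:
        write_gmt(world.catalog, outdir / "catalog.gmt")
    (outdir / "truth.json").write_text(
        json.dumps(world.truth, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
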