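"""Reading, merging and writing interaction networks, gene sets and annotation catalogs.

The network model is a simple undirected graph over gene symbols with
per-edge provenance labels.  Input formats are deliberately minimal: a
two/three-column tab-delimited edge list, a PSI-MI-TAB-like dialect of
which only the first two columns are consumed, one-symbol-per-line gene
set files, and GMT annotation catalogs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

COMMENT_PREFIXES = ("#", "!")

__all__ = [
    "InteractionRecord",
    "Interactome",
    "ProteinSet",
    "ParseError",
    "normalize_symbol",
    "parse_edge_list",
    "build_interactome",
    "map_protein_set",
    "derive_control_set",
    "read_set_file",
    "read_gmt",
    "write_edge_tsv",
    "write_graphml",
    "read_network_tsv",
]


class ParseError(ValueError):
    """Malformed input line; message carries the file and line number."""


def normalize_symbol(token: str) -> str:
    """Default symbol normalization: strip surrounding whitespace, uppercase."""
    return token.strip().upper()


@dataclass(frozen=True)
class InteractionRecord:
    """One reported interaction between two gene symbols.

    Records are orderless: ``(a, b)`` and ``(b, a)`` denote the same pair.
    """

    protein_a: str
    protein_b: str
    source: str = ""

    def pair(self) -> tuple[str, str]:
        """Canonical (lexicographically ordered) endpoint pair."""
        a, b = self.protein_a, self.protein_b
        return (a, b) if a <= b else (b, a)

    def is_self_interaction(self) -> bool:
        return self.protein_a == self.protein_b


class Interactome:
    """Simple undirected graph over gene symbols with edge provenance.

    Invariants: no self-loops, no duplicate edges; the node set is the
    union of edge endpoints plus explicitly added isolated nodes.
    """

    def __init__(self, graph: nx.Graph | None = None):
        self.graph: nx.Graph = graph if graph is not None else nx.Graph()

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> Iterable[tuple[str, str]]:
        return self.graph.edges()

    def has_edge(self, a: str, b: str) -> bool:
        return self.graph.has_edge(a, b)

    def edge_sources(self, a: str, b: str) -> set[str]:
        return set(self.graph.edges[a, b].get("sources", set()))

    def degree(self, node: str) -> int:
        return self.graph.degree[node]

    def __contains__(self, node: str) -> bool:
        return node in self.graph

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Interactome(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


@dataclass(frozen=True)
class ProteinSet:
    """A named gene set together with its subset mapped into a network."""

    name: str
    genes: frozenset[str]
    mapped: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if not self.mapped <= self.genes:
            raise ValueError("mapped must be a subset of genes")


def parse_edge_list(
    path: str | Path,
    dialect: str = "simple_tsv",
    symbol_normalizer: Callable[[str], str] = normalize_symbol,
) -> list[InteractionRecord]:
    """Parse a tab-delimited edge list into interaction records.

    ``simple_tsv`` reads columns 1-2 as symbols and an optional column 3
    as the provenance label.  ``mitab_minimal`` reads only columns 1-2
    and treats the identifiers as opaque symbols.  Lines starting with
    ``#`` or ``!`` and blank lines are skipped.  Self-pairs are kept
    (they are filtered by :func:`build_interactome`, not here).
    """
    if dialect not in ("simple_tsv", "mitab_minimal"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    path = Path(path)
    records: list[InteractionRecord] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n").rstrip("\r")
            if not stripped.strip() or stripped.lstrip().startswith(COMMENT_PREFIXES):
                continue
            fields = stripped.split("\t")
            if len(fields) < 2:
                raise ParseError(
                    f"{path}:{lineno}: expected >=2 tab-separated columns, got {len(fields)}"
                )
            a = symbol_normalizer(fields[0])
            b = symbol_normalizer(fields[1])
            if not a or not b:
                raise ParseError(f"{path}:{lineno}: empty symbol after normalization")
            source = ""
            if dialect == "simple_tsv" and len(fields) >= 3:
                source = fields[2].strip()
            records.append(InteractionRecord(a, b, source))
    return records


def build_interactome(records: Iterable[InteractionRecord]) -> Interactome:
    """Merge records into one deduplicated, self-loop-free undirected graph.

    Self-interactions are dropped; duplicate pairs (in either endpoint
    order) collapse to a single edge carrying the union of source labels.
    """
    records = list(records)
    if not records:
        raise ValueError("no interaction records supplied")
    g = nx.Graph()
    n_self = 0
    for rec in records:
        if rec.is_self_interaction():
            n_self += 1
            continue
        a, b = rec.pair()
        if g.has_edge(a, b):
            if rec.source:
                g.edges[a, b]["sources"].add(rec.source)
        else:
            sources = {rec.source} if rec.source else set()
            g.add_edge(a, b, sources=sources)
    if g.number_of_edges() == 0:
        raise ValueError("empty network: all records were self-interactions")
    logger.info(
        "built interactome: %d nodes, %d edges (%d records, %d self-interactions dropped)",
        g.number_of_nodes(), g.number_of_edges(), len(records), n_self,
    )
    return Interactome(g)


def map_protein_set(set_genes: Iterable[str], net: Interactome, name: str) -> ProteinSet:
    """Intersect a gene set with the network node set."""
    genes = frozenset(set_genes)
    mapped = frozenset(genes & net.nodes)
    logger.info("set %r: %d genes, %d mapped in network", name, len(genes), len(mapped))
    if genes and not mapped:
        logger.warning("set %r: no genes mapped in the network", name)
    return ProteinSet(name=name, genes=genes, mapped=mapped)


def derive_control_set(
    net: Interactome, excluded: Iterable[ProteinSet], name: str = "control"
) -> ProteinSet:
    """All network nodes not in any excluded set's mapped members."""
    out: set[str] = set()
    for pset in excluded:
        out |= set(pset.mapped)
    control = frozenset(net.nodes - out)
    logger.info("control set %r: %d genes", name, len(control))
    return ProteinSet(name=name, genes=control, mapped=control)


def read_set_file(
    path: str | Path, symbol_normalizer: Callable[[str], str] = normalize_symbol
) -> set[str]:
    """Read a one-symbol-per-line gene set file (comments/blanks skipped)."""
    path = Path(path)
    genes: set[str] = set()
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped or stripped.startswith(COMMENT_PREFIXES):
                continue
            genes.add(symbol_normalizer(stripped))
    return genes


def read_gmt(
    path: str | Path, symbol_normalizer: Callable[[str], str] = normalize_symbol
) -> dict[str, tuple[str, frozenset[str]]]:
    """Read a GMT catalog: ``id<TAB>description<TAB>member...`` per line.

    Duplicate member symbols within a line are collapsed.
    """
    path = Path(path)
    catalog: dict[str, tuple[str, frozenset[str]]] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n").rstrip("\r")
            if not stripped.strip() or stripped.startswith(COMMENT_PREFIXES):
                continue
            fields = stripped.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs >=3 fields, got {len(fields)}"
                )
            pid, name = fields[0].strip(), fields[1].strip()
            members = frozenset(
                symbol_normalizer(f) for f in fields[2:] if f.strip()
            )
            catalog[pid] = (name, members)
    return catalog


def write_edge_tsv(net: Interactome, path: str | Path) -> None:
    """Write the network as a canonical two/three-column TSV.

    Endpoints are lexicographically ordered within a line and lines are
    sorted, so the output is bit-exact across runs for equal graphs.
    """
    lines = []
    for a, b in net.graph.edges():
        x, y = (a, b) if a <= b else (b, a)
        sources = "|".join(sorted(net.graph.edges[a, b].get("sources", set())))
        lines.append(f"{x}\t{y}\t{sources}")
    lines.sort()
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_network_tsv(path: str | Path) -> Interactome:
    """Read a network written by :func:`write_edge_tsv` (or any simple TSV)."""
    records = parse_edge_list(path, dialect="simple_tsv")
    return build_interactome(records)


def write_graphml(net: Interactome, path: str | Path) -> None:
    """Optional GraphML export; source sets are flattened to '|'-joined strings."""
    g = nx.Graph()
    g.add_nodes_from(net.graph.nodes)
    for a, b in net.graph.edges():
        g.add_edge(a, b, sources="|".join(sorted(net.graph.edges[a, b].get("sources", set()))))
    nx.write_graphml(g, str(path))
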