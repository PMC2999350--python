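"""End-to-end orchestration: build/simulate -> profile -> compare ->
null model -> enrichment, from a single validated configuration.

All stage outputs are flat TSV/JSON with stable column order and sorted
rows; floats are printed at 6 significant digits so reruns diff clean.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compare import compare_profiles
from .enrichment import enrichment_table, filter_enriched, fisher_enrichment, top_by_measure, union_top
from .interactome import (
    Interactome,
    ProteinSet,
    build_interactome,
    derive_control_set,
    map_protein_set,
    parse_edge_list,
    read_gmt,
    read_set_file,
    write_edge_tsv,
)
from .nullmodel import induced_subnetwork, null_summaries, randomization_test, removal_effect
from .synthetic import generate_world, write_world
from .topology import MEASURES, betweenness, build_profile, clustering_coefficients

logger = logging.getLogger(__name__)

DEFAULT_HUB_CUTOFFS = (5, 12)
DEFAULT_NULL_REPS = 1000
DEFAULT_TOP_K = 20
DEFAULT_FDR = 0.001
DEFAULT_MIN_OVERLAP = 5

__all__ = ["RunConfig", "validate_config", "run_all", "write_table"]


@dataclass
class RunConfig:
    """Validated run configuration; exactly one of inputs/simulate is set."""

    outdir: Path
    inputs: dict | None = None            # {networks: [...], sets: {name: path}, catalog: path}
    simulate: dict | None = None          # kwargs for synthetic.generate_world
    pairs: list[tuple[str, str]] = field(default_factory=list)
    measures: tuple[str, ...] = MEASURES
    hub_cutoffs: tuple[int, ...] = DEFAULT_HUB_CUTOFFS
    betweenness_variant: str = "pair-dependency"
    null_set: str | None = None
    null_reps: int = DEFAULT_NULL_REPS
    enrich_set: str | None = None
    top_k: int = DEFAULT_TOP_K
    fdr_threshold: float = DEFAULT_FDR
    min_overlap: int = DEFAULT_MIN_OVERLAP
    removal_top_n: int = 4
    seed: int = 0
    derive_control: bool = True


_KNOWN_KEYS = {
    "outdir", "inputs", "simulate", "pairs", "measures", "hub_cutoffs",
    "betweenness_variant", "null_set", "null_reps", "enrich_set", "top_k",
    "fdr_threshold", "min_overlap", "removal_top_n", "seed", "derive_control",
}


def validate_config(raw: str | Mapping[str, Any]) -> RunConfig:
    """Parse and range-check a YAML/dict configuration, filling defaults."""
    if isinstance(raw, str):
        raw = yaml.safe_load(raw)
    if not isinstance(raw, Mapping) or not raw:
        raise ValueError(
            "empty config: required fields are 'outdir' and exactly one of "
            "'inputs' (networks/sets paths) or 'simulate' (generator block)"
        )
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "outdir" not in raw:
        raise ValueError("missing required field: outdir")
    has_inputs = raw.get("inputs") is not None
    has_sim = raw.get("simulate") is not None
    if has_inputs == has_sim:
        raise ValueError("config must contain exactly one of 'inputs' or 'simulate'")

    cfg = RunConfig(
        outdir=Path(raw["outdir"]),
        inputs=dict(raw["inputs"]) if has_inputs else None,
        simulate=dict(raw["simulate"]) if has_sim else None,
        pairs=[tuple(str(p).split(":", 1)) if isinstance(p, str) else tuple(p)
               for p in raw.get("pairs", [])],
        measures=tuple(raw.get("measures", MEASURES)),
        hub_cutoffs=tuple(int(c) for c in raw.get("hub_cutoffs", DEFAULT_HUB_CUTOFFS)),
        betweenness_variant=str(raw.get("betweenness_variant", "pair-dependency")),
        null_set=raw.get("null_set"),
        null_reps=int(raw.get("null_reps", DEFAULT_NULL_REPS)),
        enrich_set=raw.get("enrich_set"),
        top_k=int(raw.get("top_k", DEFAULT_TOP_K)),
        fdr_threshold=float(raw.get("fdr_threshold", DEFAULT_FDR)),
        min_overlap=int(raw.get("min_overlap", DEFAULT_MIN_OVERLAP)),
        removal_top_n=int(raw.get("removal_top_n", 4)),
        seed=int(raw.get("seed", 0)),
        derive_control=bool(raw.get("derive_control", True)),
    )
    if cfg.null_reps < 1:
        raise ValueError("null_reps must be >= 1")
    if cfg.top_k < 1:
        raise ValueError("top_k must be >= 1")
    if not (0.0 < cfg.fdr_threshold <= 1.0):
        raise ValueError("fdr_threshold must lie in (0,1]")
    if cfg.min_overlap < 0:
        raise ValueError("min_overlap must be >= 0")
    for m in cfg.measures:
        if m not in MEASURES:
            raise ValueError(f"unknown measure: {m!r}")
    if cfg.betweenness_variant not in ("pair-dependency", "raw-count"):
        raise ValueError(f"unknown betweenness variant: {cfg.betweenness_variant!r}")
    for pair in cfg.pairs:
        if len(pair) != 2:
            raise ValueError(f"pair must have two set labels: {pair}")
    return cfg


def _fmt(x: Any) -> str:
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)


def write_table(df: pd.DataFrame, path: Path) -> None:
    """TSV writer with 6-significant-digit floats and no index column."""
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(_fmt)
    out.to_csv(path, sep="\t", index=False)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_inputs(cfg: RunConfig) -> tuple[Interactome, dict[str, ProteinSet], dict, dict]:
    inputs = cfg.inputs or {}
    networks = inputs.get("networks")
    if not networks:
        raise ValueError("inputs.networks must list at least one edge-list file")
    records = []
    checksums = {}
    for entry in networks:
        if isinstance(entry, str):
            path, dialect = entry, "simple_tsv"
        else:
            path, dialect = entry["path"], entry.get("dialect", "simple_tsv")
        records.extend(parse_edge_list(path, dialect=dialect))
        checksums[str(path)] = _sha256(Path(path))
    net = build_interactome(records)
    sets: dict[str, ProteinSet] = {}
    for name, path in (inputs.get("sets") or {}).items():
        sets[name] = map_protein_set(read_set_file(path), net, name)
        checksums[str(path)] = _sha256(Path(path))
    catalog = {}
    if inputs.get("catalog"):
        catalog = read_gmt(inputs["catalog"])
        checksums[str(inputs["catalog"])] = _sha256(Path(inputs["catalog"]))
    return net, sets, catalog, checksums


def run_all(cfg: RunConfig) -> dict[str, Path]:
    """Execute the full analysis; returns the paths of the emitted bundle."""
    outdir = cfg.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    log: dict[str, Any] = {
        "version": __version__,
        "seed": cfg.seed,
        "betweenness_variant": cfg.betweenness_variant,
    }

    stage = "inputs"
    try:
        if cfg.simulate is not None:
            world = generate_world(seed=cfg.seed, **cfg.simulate)
            write_world(world, outdir / "world")
            net, sets, catalog = world.net, dict(world.sets), world.catalog
            log["truth"] = world.truth
            artifacts["world"] = outdir / "world"
            checksums = {}
        else:
            net, sets, catalog, checksums = _load_inputs(cfg)
        log["input_checksums"] = checksums
        log["network"] = {"n_nodes": net.n_nodes, "n_edges": net.n_edges}

        if cfg.derive_control and "control" not in sets:
            sets["control"] = derive_control_set(net, list(sets.values()))

        stage = "network_export"
        write_edge_tsv(net, outdir / "network.tsv")
        artifacts["network"] = outdir / "network.tsv"

        stage = "topology"
        B = betweenness(net, cfg.betweenness_variant)
        C = clustering_coefficients(net)
        profiles = {
            name: build_profile(net, pset, precomputed_B=B, precomputed_C=C)
            for name, pset in sets.items()
            if pset.mapped
        }
        summary = pd.DataFrame(
            [profiles[name].summary_row(cfg.hub_cutoffs) for name in sorted(profiles)]
        )
        write_table(summary, outdir / "set_summary.tsv")
        artifacts["set_summary"] = outdir / "set_summary.tsv"
        for name in sorted(profiles):
            per_node = profiles[name].table.reset_index()
            write_table(per_node, outdir / f"profile_{name}.tsv")
            artifacts[f"profile_{name}"] = outdir / f"profile_{name}.tsv"

        stage = "compare"
        pairs = cfg.pairs
        if not pairs:
            names = sorted(profiles)
            pairs = [(names[i], names[j]) for i in range(len(names)) for j in range(i + 1, len(names))]
        comparisons = compare_profiles(profiles, pairs, cfg.measures, cfg.hub_cutoffs)
        write_table(comparisons, outdir / "comparisons.tsv")
        artifacts["comparisons"] = outdir / "comparisons.tsv"

        stage = "nullmodel"
        null_name = cfg.null_set or sorted(profiles)[0]
        if null_name not in sets:
            raise ValueError(f"null_set {null_name!r} is not a configured set")
        sub = induced_subnetwork(net, sets[null_name])
        linked = sub.linked_graph()
        if linked.number_of_edges() > 0:
            observed = null_summaries(linked)
            result = randomization_test(
                observed, linked.number_of_nodes(), linked.number_of_edges(),
                reps=cfg.null_reps, seed=cfg.seed,
            )
            null_report: dict[str, Any] = {
                "set": null_name,
                "subnetwork": {
                    "n_members": sub.n_nodes,
                    "n_linked": sub.n_linked,
                    "n_edges": sub.n_edges,
                    "n_components": len(sub.components),
                    "component_sizes": [len(c) for c in sub.components],
                },
                "null_model": result.to_dict(),
            }
            if linked.number_of_nodes() >= 3 + cfg.removal_top_n:
                by_degree = sorted(linked.degree(), key=lambda kv: (-kv[1], kv[0]))
                top_nodes = [v for v, _ in by_degree[: cfg.removal_top_n]]
                report = removal_effect(linked, top_nodes)
                null_report["centralization"] = {
                    "before": report.before,
                    "after": report.after,
                    "removed": report.removed,
                }
            (outdir / "null_model.json").write_text(
                json.dumps(null_report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
            )
            artifacts["null_model"] = outdir / "null_model.json"
        else:
            logger.warning("set %r has no within-set edges; null model skipped", null_name)

        stage = "enrichment"
        if catalog:
            enrich_name = cfg.enrich_set or null_name
            if enrich_name not in profiles:
                raise ValueError(f"enrich_set {enrich_name!r} is not a profiled set")
            prof = profiles[enrich_name]
            tops = {m: top_by_measure(prof, m, cfg.top_k) for m in cfg.measures}
            selected, flags = union_top(tops)
            write_table(flags.reset_index(), outdir / "top_membership.tsv")
            rows = fisher_enrichment(selected, catalog, net.nodes)
            kept = filter_enriched(rows, cfg.fdr_threshold, cfg.min_overlap)
            write_table(enrichment_table(kept), outdir / "enrichment.tsv")
            write_table(
                enrichment_table(sorted(rows, key=lambda r: (r.fdr_p, r.p_value, r.pathway_id))),
                outdir / "enrichment_all.tsv",
            )
            artifacts["enrichment"] = outdir / "enrichment.tsv"
            log["enrichment"] = {
                "set": enrich_name, "top_k": cfg.top_k,
                "n_selected": len(selected), "n_pathways_tested": len(rows),
                "n_pathways_enriched": len(kept),
            }

        stage = "run_log"
        (outdir / "run_log.json").write_text(
            json.dumps(log, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        artifacts["run_log"] = outdir / "run_log.json"
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return artifacts
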