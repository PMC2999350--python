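"""Top-ranked protein selection and pathway over-representation analysis.

Proteins are ranked per topological measure (descending for k, B, C;
ascending for gSPD and cSPD), the per-measure top lists are unioned, and
each catalog pathway is tested for over-representation with a one-sided
Fisher (hypergeometric tail) test followed by Benjamini-Hochberg FDR
adjustment and criterion filtering.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .topology import MEASURES, TopologyProfile

logger = logging.getLogger(__name__)

ASCENDING_MEASURES = ("gSPD", "cSPD")  # shorter distance ranks higher

__all__ = [
    "EnrichmentRow",
    "top_by_measure",
    "union_top",
    "fisher_pvalue",
    "fisher_enrichment",
    "bh_fdr",
    "filter_enriched",
    "enrichment_table",
]


@dataclass(frozen=True)
class EnrichmentRow:
    pathway_id: str
    pathway_name: str
    n_overlap: int
    n_pathway: int
    n_selected: int
    n_background: int
    p_value: float
    fdr_p: float

    def __post_init__(self):
        if self.n_overlap > min(self.n_pathway, self.n_selected):
            raise ValueError("overlap exceeds pathway or selection size")
        for p in (self.p_value, self.fdr_p):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"p-value out of [0,1]: {p}")


def top_by_measure(
    profile: TopologyProfile,
    measure: str,
    k: int = 20,
    direction: str | None = None,
) -> list[str]:
    """Top-k nodes by one measure; ties broken lexicographically by node id.

    ``direction`` defaults to descending for k, B, C and ascending for
    gSPD and cSPD.  Nodes with undefined (NaN) values are excluded; if
    fewer than k remain, all are returned with a warning.
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure: {measure!r}")
    if k < 1:
        raise ValueError("k must be >= 1")
    if direction is None:
        direction = "asc" if measure in ASCENDING_MEASURES else "desc"
    if direction not in ("asc", "desc"):
        raise ValueError(f"direction must be 'asc' or 'desc', got {direction!r}")
    col = profile.table[measure]
    defined = col[~col.isna()]
    if len(defined) < k:
        logger.warning(
            "set %r: only %d defined %s values for top-%d selection",
            profile.set_name, len(defined), measure, k,
        )
    sign = -1.0 if direction == "desc" else 1.0
    ranked = sorted(defined.items(), key=lambda item: (sign * item[1], item[0]))
    return [node for node, _ in ranked[:k]]


def union_top(lists: Mapping[str, Sequence[str]]) -> tuple[set[str], pd.DataFrame]:
    """Union of per-measure top lists plus a per-list membership table."""
    union: set[str] = set()
    for members in lists.values():
        union |= set(members)
    flags = pd.DataFrame(
        {label: [node in set(members) for node in sorted(union)]
         for label, members in lists.items()},
        index=pd.Index(sorted(union), name="node"),
    )
    return union, flags


def fisher_pvalue(n_overlap: int, n_pathway: int, n_selected: int, n_background: int) -> float:
    """One-sided over-representation p: P(X >= n_overlap), X hypergeometric."""
    return float(stats.hypergeom.sf(n_overlap - 1, n_background, n_pathway, n_selected))


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment; output order matches input."""
    ps = np.asarray(p_values, dtype=float)
    if ps.size == 0:
        return []
    if np.any((ps < 0) | (ps > 1)) or np.any(np.isnan(ps)):
        raise ValueError("p-values must lie in [0,1]")
    n = ps.size
    order = np.argsort(ps, kind="stable")
    ranked = ps[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(n)
    out[order] = adjusted
    return out.tolist()


def fisher_enrichment(
    selected: Iterable[str],
    catalog: Mapping[str, tuple[str, frozenset[str]]],
    background: Iterable[str],
) -> list[EnrichmentRow]:
    """Per-pathway over-representation of ``selected`` within ``background``.

    Pathway membership is restricted to the background before counting.
    Rows carry both the raw Fisher p and its BH-FDR adjustment across
    all tested pathways; they are returned in catalog-id order.
    """
    bg = set(background)
    if not bg:
        raise ValueError("empty background")
    sel = set(selected)
    if not sel <= bg:
        raise ValueError("selected genes must be a subset of the background")
    pids = sorted(catalog)
    raw: list[tuple[str, str, int, int]] = []
    for pid in pids:
        name, members = catalog[pid]
        in_bg = set(members) & bg
        raw.append((pid, name, len(in_bg & sel), len(in_bg)))
    ps = [fisher_pvalue(k, K, len(sel), len(bg)) for _, _, k, K in raw]
    fdrs = bh_fdr(ps)
    return [
        EnrichmentRow(
            pathway_id=pid, pathway_name=name,
            n_overlap=k, n_pathway=K, n_selected=len(sel), n_background=len(bg),
            p_value=p, fdr_p=q,
        )
        for (pid, name, k, K), p, q in zip(raw, ps, fdrs)
    ]


def filter_enriched(
    rows: Iterable[EnrichmentRow],
    fdr_threshold: float = 0.001,
    min_overlap: int = 5,
) -> list[EnrichmentRow]:
    """Keep rows with fdr_p strictly below threshold and overlap >= minimum.

    Output is sorted by fdr_p, then raw p, then pathway id.
    """
    if not (0.0 < fdr_threshold <= 1.0):
        raise ValueError("fdr_threshold must lie in (0,1]")
    if min_overlap < 0:
        raise ValueError("min_overlap must be >= 0")
    kept = [r for r in rows if r.fdr_p < fdr_threshold and r.n_overlap >= min_overlap]
    kept.sort(key=lambda r: (r.fdr_p, r.p_value, r.pathway_id))
    return kept


def enrichment_table(rows: Iterable[EnrichmentRow]) -> pd.DataFrame:
    """Flat table of enrichment rows (ranked output shape)."""
    df = pd.DataFrame([r.__dict__ for r in rows])
    if not df.empty:
        df.insert(0, "rank", range(1, len(df) + 1))
    return df
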