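"""Hypergeometric over-representation analysis and DAG export.

For a query list of n genes drawn from a background universe of M genes, a
category with K members (after intersecting with the background) and Q query
hits is scored by the upper-tail hypergeometric probability P(X >= Q);
Benjamini-Hochberg FDR is applied across all tested categories.  A category
is significant when q < fdr_threshold and Q >= min_query_elements.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .ontology import Ontology


@dataclasses.dataclass(frozen=True)
class EnrichmentConfig:
    """Significance thresholds.  The defaults (FDR < 0.005 with at least
    five query elements in the category) are deliberately strict: pathway
    summaries should only show robustly enriched categories."""

    fdr_threshold: float = 0.005
    min_query_elements: int = 5
    query_mode: str = "combined"  # 'combined', 'up' or 'down'

    def __post_init__(self) -> None:
        if not 0 < self.fdr_threshold < 1:
            raise ValueError("fdr_threshold must lie in (0, 1)")
        if self.min_query_elements < 1:
            raise ValueError("min_query_elements must be >= 1")
        if self.query_mode not in ("combined", "up", "down"):
            raise ValueError("query_mode must be 'combined', 'up' or 'down'")


@dataclasses.dataclass(eq=False)
class EnrichmentResult:
    """Per-category table with columns ``name``, ``category_size``,
    ``query_elements``, ``p``, ``q``, ``significant``; indexed by category
    ID."""

    table: pd.DataFrame
    background_size: int
    query_size: int
    ontology_key: str
    background: frozenset[str]

    @property
    def significant_ids(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


def enrich(
    query: Iterable[str],
    ontology: Ontology,
    background: Iterable[str],
    config: EnrichmentConfig | None = None,
) -> EnrichmentResult:
    """Hypergeometric ORA of a query gene list against an ontology.

    Category members are intersected with the background before testing;
    categories with no members in the background are skipped.
    """
    cfg = config or EnrichmentConfig()
    background = frozenset(background)
    query = frozenset(query)
    if not background:
        raise ValueError("background universe is empty")
    if not query:
        raise ValueError("query gene list is empty")
    stray = query - background
    if stray:
        raise ValueError(f"query genes outside background: {sorted(stray)[:5]}")

    M = len(background)
    n = len(query)
    rows = []
    for cid, gs in ontology.categories.items():
        members = gs.members & background
        K = len(members)
        if K == 0:
            continue
        Q = len(query & members)
        p = float(hypergeom.sf(Q - 1, M, K, n))
        rows.append((cid, gs.name, K, Q, p))
    if not rows:
        raise ValueError("no ontology category overlaps the background")
    table = pd.DataFrame(
        rows, columns=["category_id", "name", "category_size", "query_elements", "p"]
    ).set_index("category_id")
    table["q"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    table["significant"] = (table["q"] < cfg.fdr_threshold) & (
        table["query_elements"] >= cfg.min_query_elements
    )
    return EnrichmentResult(
        table=table,
        background_size=M,
        query_size=n,
        ontology_key=ontology.digest(),
        background=background,
    )


def query_from_classes(classes: pd.Series | np.ndarray, probes: list[str], mode: str) -> set[str]:
    """Build a query gene list from one sample's ternary calls."""
    codes = np.asarray(classes)
    if mode == "combined":
        mask = codes != 0
    elif mode == "up":
        mask = codes == 1
    elif mode == "down":
        mask = codes == -1
    else:
        raise ValueError(f"unknown query mode {mode!r}")
    return {p for p, m in zip(probes, mask) if m}


def _dot_quote(s: str) -> str:
    return '"' + s.replace('"', '\\"') + '"'


def export_dag(
    result: EnrichmentResult, ontology: Ontology, path: str | Path | None = None
) -> str:
    """Emit a DOT graph of the significant categories plus their ancestors.

    Node attributes carry ``neglog10_q`` (colour intensity in a renderer)
    and ``query_elements`` (node size).  Returns the DOT text; also writes
    it when ``path`` is given.
    """
    if ontology.parent_edges is None:
        raise ValueError("ontology has no parent_edges; cannot build a DAG summary")
    sig = set(result.significant_ids)
    nodes = set(sig)
    for cid in sig:
        nodes |= ontology.ancestors(cid)
    lines = ["digraph enrichment {"]
    for cid in sorted(nodes):
        attrs = [f"label={_dot_quote(ontology.categories[cid].name)}"]
        if cid in result.table.index:
            row = result.table.loc[cid]
            neglog = -np.log10(max(float(row["q"]), 1e-300))
            attrs.append(f'neglog10_q="{neglog:.6g}"')
            attrs.append(f'query_elements="{int(row["query_elements"])}"')
        if cid in sig:
            attrs.append('significant="true"')
        lines.append(f"  {_dot_quote(cid)} [{', '.join(attrs)}];")
    for child, parent in ontology.parent_edges:
        if child in nodes and parent in nodes:
            lines.append(f"  {_dot_quote(child)} -> {_dot_quote(parent)};")
    lines.append("}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
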