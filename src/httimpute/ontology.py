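"""Gene-set ontologies: GMT categories plus an optional parent DAG."""
from __future__ import annotations

import dataclasses
import hashlib
import warnings
from pathlib import Path
from typing import Iterable

import networkx as nx


@dataclasses.dataclass(frozen=True)
class GeneSet:
    id: str
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not isinstance(self.members, frozenset):
            object.__setattr__(self, "members", frozenset(self.members))
        if not self.members:
            raise ValueError(f"gene set {self.id!r} has no members")


@dataclasses.dataclass(eq=False)
class Ontology:
    """Categories keyed by ID, with optional acyclic (child, parent) edges.

    The parent relation summarises enrichment results on a DAG, with broad
    categories (e.g. "metabolism") as ancestors of discrete pathways.
    """

    categories: dict[str, GeneSet]
    parent_edges: tuple[tuple[str, str], ...] | None = None

    def __post_init__(self) -> None:
        if not self.categories:
            raise ValueError("ontology has no categories")
        if self.parent_edges is not None:
            self.parent_edges = tuple(tuple(e) for e in self.parent_edges)
            unknown = {
                n for e in self.parent_edges for n in e if n not in self.categories
            }
            if unknown:
                raise ValueError(
                    f"parent_edges reference unknown categories: {sorted(unknown)[:5]}"
                )
            if not nx.is_directed_acyclic_graph(self.graph()):
                raise ValueError("parent_edges contain a cycle")

    def graph(self) -> nx.DiGraph:
        """Directed graph with child -> parent edges over all categories."""
        g = nx.DiGraph()
        g.add_nodes_from(self.categories)
        if self.parent_edges:
            g.add_edges_from(self.parent_edges)
        return g

    def ancestors(self, category_id: str) -> set[str]:
        if self.parent_edges is None:
            return set()
        return nx.descendants(self.graph(), category_id)  # child->parent orientation

    def digest(self) -> str:
        """Stable digest of the membership structure, used to detect that two
        enrichment results were computed against the same ontology."""
        h = hashlib.sha1()
        for cid in sorted(self.categories):
            h.update(cid.encode())
            h.update(b"\x00")
            for m in sorted(self.categories[cid].members):
                h.update(m.encode())
                h.update(b"\x01")
        return h.hexdigest()


def read_gmt(path: str | Path) -> Ontology:
    """Read a GMT file (category, description, tab-separated members)."""
    categories: dict[str, GeneSet] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: malformed GMT line {lineno} (need >=2 fields)")
            cid, desc, *members = fields
            members = [m for m in members if m]
            if not members:
                warnings.warn(f"{path}: empty gene set {cid!r} at line {lineno}; skipped")
                continue
            if cid in categories:
                raise ValueError(f"{path}: duplicate category {cid!r} at line {lineno}")
            categories[cid] = GeneSet(cid, desc or cid, frozenset(members))
    return Ontology(categories)


def write_gmt(ontology: Ontology, path: str | Path) -> None:
    with open(path, "w") as fh:
        for cid in ontology.categories:
            gs = ontology.categories[cid]
            fh.write("\t".join([gs.id, gs.name, *sorted(gs.members)]) + "\n")


def read_parent_edges(path: str | Path) -> tuple[tuple[str, str], ...]:
    """Read a 2-column TSV of (child, parent) category IDs."""
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}: malformed edge line {lineno} (need 2 fields)")
            edges.append((fields[0], fields[1]))
    return tuple(edges)


def with_parent_edges(ontology: Ontology, edges: Iterable[tuple[str, str]]) -> Ontology:
    return Ontology(dict(ontology.categories), tuple(edges))
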