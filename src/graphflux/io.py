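"""Readers, writers and the core graph data model.

The reference interactome is an undirected weighted graph R(V, E, c(e))
with per-edge confidence scores in (0, 1].  Seeds are the omic hits
(proteins/genes of interest) that drive inference, each with a positive
weight.  Annotation collections carry gene sets (GMT) for the
hypergeometric enrichment step.
"""

from __future__ import annotations

import logging
import os
import tempfile
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "Interactome",
    "SeedSet",
    "AnnotationCollection",
    "load_interactome",
    "load_seeds",
    "load_gmt",
    "write_network",
    "read_network",
]


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


class ValidationError(ValueError):
    """Input violates a data-model invariant."""


class Interactome:
    """Undirected weighted interactome with confidences in (0, 1].

    Invariants: no self-loops, unordered pairs unique, every confidence
    strictly positive and at most 1, every edge endpoint in the node set.
    Node identifiers are case-sensitive opaque strings.
    """

    def __init__(self, graph: nx.Graph | None = None):
        self.graph = graph if graph is not None else nx.Graph()
        self._validate()

    def _validate(self) -> None:
        for u, v, data in self.graph.edges(data=True):
            if u == v:
                raise ValidationError(f"self-loop on node {u!r}")
            c = data.get("confidence")
            if c is None or not (0.0 < c <= 1.0):
                raise ValidationError(
                    f"edge ({u!r}, {v!r}) confidence {c!r} outside (0, 1]"
                )

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str, float]]) -> "Interactome":
        """Build from (u, v, confidence) triples.

        Self-loops are dropped; duplicate unordered pairs keep the maximum
        confidence (confidence is evidence strength; max is conservative
        toward inclusion).
        """
        g = nx.Graph()
        for u, v, c in edges:
            if u == v:
                continue
            if g.has_edge(u, v):
                g[u][v]["confidence"] = max(g[u][v]["confidence"], float(c))
            else:
                g.add_edge(u, v, confidence=float(c))
        return cls(g)

    # -- read-only views -------------------------------------------------
    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset((u, v)) for u, v in self.graph.edges}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def confidence(self, u: str, v: str) -> float:
        return self.graph[u][v]["confidence"]

    def degree(self, node: str) -> int:
        return self.graph.degree(node)

    def has_edge(self, u: str, v: str) -> bool:
        return self.graph.has_edge(u, v)

    def neighbors(self, node: str):
        return self.graph.neighbors(node)

    def copy(self) -> "Interactome":
        return Interactome(self.graph.copy())

    def edge_subgraph(
        self, edges: Iterable[tuple[str, str]], extra_nodes: Iterable[str] = ()
    ) -> "Interactome":
        """Subgraph on an explicit edge subset (confidences inherited)."""
        g = nx.Graph()
        for u, v in edges:
            g.add_edge(u, v, confidence=self.graph[u][v]["confidence"])
        for n in extra_nodes:
            g.add_node(n)
        return Interactome(g)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Interactome):
            return NotImplemented
        if self.nodes != other.nodes or self.edges != other.edges:
            return False
        return all(
            self.confidence(*sorted(e)) == other.confidence(*sorted(e))
            for e in self.edges
        )

    def __repr__(self) -> str:
        return f"Interactome({self.n_nodes} nodes, {self.n_edges} edges)"


@dataclass
class SeedSet:
    """Seed nodes (omic hits) with positive weights.

    ``coverage`` is the fraction of the input seeds that were found in the
    interactome; seeds absent from the interactome are dropped.
    """

    weights: dict[str, float]
    coverage: float = 1.0

    def __post_init__(self):
        for node, w in self.weights.items():
            if w <= 0:
                raise ValidationError(f"seed {node!r} has non-positive weight {w}")

    @classmethod
    def from_nodes(
        cls,
        nodes: Iterable[str] | Mapping[str, float],
        interactome: Interactome | None = None,
    ) -> "SeedSet":
        """Build from node ids (default weight 1.0) or a node->weight map."""
        if isinstance(nodes, Mapping):
            raw = {str(k): float(v) for k, v in nodes.items()}
        else:
            raw = {str(n): 1.0 for n in nodes}
        if interactome is None:
            return cls(weights=raw, coverage=1.0)
        kept = {n: w for n, w in raw.items() if n in interactome.nodes}
        dropped = set(raw) - set(kept)
        if dropped:
            logger.warning(
                "%d of %d seeds absent from the interactome: %s",
                len(dropped), len(raw), sorted(dropped)[:10],
            )
        if not kept:
            raise ValidationError("no input seed maps to the interactome")
        return cls(weights=kept, coverage=len(kept) / len(raw))

    @property
    def nodes(self) -> set[str]:
        return set(self.weights)

    def __len__(self) -> int:
        return len(self.weights)

    def __contains__(self, node) -> bool:
        return node in self.weights


@dataclass
class AnnotationCollection:
    """Gene sets for enrichment: term id -> (term name, member nodes)."""

    sets: dict[str, tuple[str, frozenset]]
    universe: set[str] | None = None

    def __post_init__(self):
        for term, (_, members) in self.sets.items():
            if not members:
                raise ValidationError(f"annotation term {term!r} is empty")
        if self.universe is not None:
            annotated = set().union(*(m for _, m in self.sets.values()))
            missing = annotated - self.universe
            if missing:
                # enforce the invariant by widening the universe
                self.universe = self.universe | missing

    @property
    def annotated_nodes(self) -> set[str]:
        return set().union(*(m for _, m in self.sets.values()))

    def members(self, term: str) -> frozenset:
        return self.sets[term][1]


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def _data_lines(path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def load_interactome(path: str, default_confidence: float = 1.0) -> Interactome:
    """Read a tab-separated edge list (node_a, node_b[, confidence]).

    Rows with a missing third column take ``default_confidence`` (an
    unweighted interactome gets confidence 1.0 throughout by default).
    Self-loops are dropped; duplicate pairs keep the maximum confidence.
    Lines starting with '#' are comments.
    """
    if not (0.0 < default_confidence <= 1.0):
        raise ValidationError(
            f"default_confidence {default_confidence} outside (0, 1]"
        )
    triples = []
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) not in (2, 3):
            raise ParseError(
                f"{path}:{lineno}: expected 2 or 3 tab-separated columns, "
                f"got {len(parts)}"
            )
        u, v = parts[0].strip(), parts[1].strip()
        if not u or not v:
            raise ParseError(f"{path}:{lineno}: empty node identifier")
        if len(parts) == 3:
            try:
                c = float(parts[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: confidence {parts[2]!r} is not a number"
                ) from exc
            if not (0.0 < c <= 1.0):
                raise ValidationError(
                    f"{path}:{lineno}: confidence {c} outside (0, 1]"
                )
        else:
            c = default_confidence
        triples.append((u, v, c))
    return Interactome.from_edges(triples)


def load_seeds(path: str, interactome: Interactome) -> SeedSet:
    """Read a seed table (node[, weight]); weightless seeds get 1.0.

    Seeds absent from the interactome are dropped with a warning and
    reflected in ``coverage``; zero retained seeds is a fatal error.
    """
    raw: dict[str, float] = {}
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) not in (1, 2):
            raise ParseError(
                f"{path}:{lineno}: expected 1 or 2 tab-separated columns, "
                f"got {len(parts)}"
            )
        node = parts[0].strip()
        if not node:
            raise ParseError(f"{path}:{lineno}: empty node identifier")
        if len(parts) == 2 and parts[1].strip():
            try:
                w = float(parts[1])
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: weight {parts[1]!r} is not a number"
                ) from exc
            if w <= 0:
                raise ValidationError(f"{path}:{lineno}: non-positive weight {w}")
        else:
            w = 1.0
        raw[node] = w
    if not raw:
        raise ValidationError(f"{path}: no seeds found")
    return SeedSet.from_nodes(raw, interactome)


def load_gmt(path: str, universe: set[str] | None = None) -> AnnotationCollection:
    """Read standard GMT: term <TAB> description <TAB> gene ..."""
    sets: dict[str, tuple[str, frozenset]] = {}
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) < 3:
            raise ParseError(
                f"{path}:{lineno}: GMT rows need term, description and "
                f"at least one gene"
            )
        term, desc = parts[0].strip(), parts[1].strip()
        members = frozenset(p.strip() for p in parts[2:] if p.strip())
        if not members:
            raise ParseError(f"{path}:{lineno}: term {term!r} has no genes")
        sets[term] = (desc, members)
    return AnnotationCollection(sets=sets, universe=universe)


def write_interactome(interactome: Interactome, path: str) -> None:
    """Write a plain 3-column interactome TSV."""
    rows = ["#node_a\tnode_b\tconfidence"]
    for u, v in sorted(map(sorted, interactome.graph.edges())):
        rows.append(f"{u}\t{v}\t{interactome.confidence(u, v):.17g}")
    atomic_write(path, "\n".join(rows) + "\n")


def write_network(network, path: str, format: str = "tsv") -> None:
    """Write an inferred context network with its scores.

    TSV columns: node_a, node_b, confidence, min_flux, f_e, selected_rank.
    GraphML carries the same edge attributes.
    """
    g = network.graph
    if format == "tsv":
        rows = ["#node_a\tnode_b\tconfidence\tmin_flux\tf_e\tselected_rank"]
        for u, v in sorted(map(sorted, g.edges())):
            d = g[u][v]
            rows.append(
                f"{u}\t{v}\t{d['confidence']:.12g}\t{d['min_flux']:.12g}"
                f"\t{d['f_e']:.12g}\t{d['selected_rank']}"
            )
        atomic_write(path, "\n".join(rows) + "\n")
    elif format == "graphml":
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_network(path: str):
    """Read back a context-network TSV written by :func:`write_network`."""
    from .propagation import ContextNetwork

    g = nx.Graph()
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) != 6:
            raise ParseError(f"{path}:{lineno}: expected 6 columns")
        u, v, c, mf, fe, rank = parts
        g.add_edge(
            u, v,
            confidence=float(c), min_flux=float(mf), f_e=float(fe),
            selected_rank=int(rank),
        )
    total = sum(d["f_e"] for _, _, d in g.edges(data=True))
    return ContextNetwork(graph=g, tau=float("nan"), total_flux=total)


def atomic_write(path: str, text: str) -> None:
    """Write text to ``path`` atomically (temp file + rename)."""
    directory = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=directory, prefix=".tmp-graphflux-")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
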