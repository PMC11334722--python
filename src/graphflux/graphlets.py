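"""Seed-constrained graphlet census and the graphlet-guided network (GGN).

Graphlets are the nine connected non-isomorphic undirected graphs on 2-4
nodes (G0-G8).  A graphlet occurrence is counted only when it covers the
seed set in a constrained way: one node in a maximum-degree orbit acts as
the *intermediate* and every remaining node is a seed (G0, the single
edge, requires both endpoints to be seeds).  Observed counts are compared
against counts on degree-preserving permuted networks with a one-sided
z-test; the union of all occurrences of significantly frequent graphlets
forms the GGN, a trimmed subgraph of the reference interactome.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .io import Interactome, SeedSet

logger = logging.getLogger(__name__)

__all__ = [
    "GraphletType",
    "GraphletMatch",
    "GraphletCensus",
    "GGN",
    "graphlet_catalogue",
    "count_constrained",
    "count_all_constrained",
    "permute_network",
    "graphlet_significance",
    "build_ggn",
]

GRAPHLET_IDS = tuple(f"G{i}" for i in range(9))


@dataclass(frozen=True)
class GraphletType:
    """One of the nine 2-4-node graphlet patterns.

    ``edge_pattern`` is on node indices 0..order-1; ``orbits`` partitions
    the indices into automorphism orbits; ``intermediate_orbit`` is the
    orbit of maximum degree within the pattern (the positions an
    intermediate node may occupy).
    """

    id: str
    order: int
    edge_pattern: frozenset
    orbits: tuple
    intermediate_orbit: frozenset

    @property
    def n_edges(self) -> int:
        return len(self.edge_pattern)


def _mk(gid, order, edges, orbits, intermediate):
    return GraphletType(
        id=gid,
        order=order,
        edge_pattern=frozenset(frozenset(e) for e in edges),
        orbits=tuple(frozenset(o) for o in orbits),
        intermediate_orbit=frozenset(intermediate),
    )


_CATALOGUE = (
    # single edge
    _mk("G0", 2, [(0, 1)], [{0, 1}], {0, 1}),
    # 3-path (one intermediate joining two seeds)
    _mk("G1", 3, [(0, 1), (1, 2)], [{0, 2}, {1}], {1}),
    # triangle
    _mk("G2", 3, [(0, 1), (1, 2), (0, 2)], [{0, 1, 2}], {0, 1, 2}),
    # 4-path
    _mk("G3", 4, [(0, 1), (1, 2), (2, 3)], [{0, 3}, {1, 2}], {1, 2}),
    # 3-star (centre 0)
    _mk("G4", 4, [(0, 1), (0, 2), (0, 3)], [{0}, {1, 2, 3}], {0}),
    # 4-cycle
    _mk("G5", 4, [(0, 1), (1, 2), (2, 3), (3, 0)], [{0, 1, 2, 3}], {0, 1, 2, 3}),
    # triangle with pendant (0 is the degree-3 apex)
    _mk("G6", 4, [(0, 1), (0, 2), (1, 2), (0, 3)], [{0}, {1, 2}, {3}], {0}),
    # diamond (K4 minus the 2-3 edge)
    _mk("G7", 4, [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3)], [{0, 1}, {2, 3}], {0, 1}),
    # 4-clique
    _mk("G8", 4, [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)],
        [{0, 1, 2, 3}], {0, 1, 2, 3}),
)


def graphlet_catalogue() -> tuple[GraphletType, ...]:
    """The nine graphlets G0-G8, ordered by (order, edge count)."""
    return _CATALOGUE


def _classify(order: int, n_edges: int, max_deg: int) -> str:
    """Map an induced connected subgraph to its graphlet id."""
    if order == 2:
        return "G0"
    if order == 3:
        return "G1" if n_edges == 2 else "G2"
    if n_edges == 3:
        return "G4" if max_deg == 3 else "G3"
    if n_edges == 4:
        return "G6" if max_deg == 3 else "G5"
    return "G7" if n_edges == 5 else "G8"


@dataclass(frozen=True)
class GraphletMatch:
    """A counted occurrence: the node subset and its intermediate."""

    graphlet: str
    nodes: frozenset
    intermediate: str | None
    edges: frozenset


@dataclass
class GraphletCensus:
    """Observed counts, permutation null and z-test verdicts per graphlet."""

    observed: dict[str, int]
    perm_counts: dict[str, list[int]]
    z: dict[str, float]
    significant: dict[str, bool]
    alpha_z: float = 1.65

    def to_rows(self):
        rows = []
        for gid in GRAPHLET_IDS:
            perm = self.perm_counts.get(gid, [])
            mean = float(np.mean(perm)) if perm else float("nan")
            sd = float(np.std(perm, ddof=1)) if len(perm) > 1 else float("nan")
            rows.append(
                dict(graphlet=gid, observed=self.observed.get(gid, 0),
                     perm_mean=mean, perm_sd=sd, z=self.z.get(gid, float("nan")),
                     significant=self.significant.get(gid, False))
            )
        return rows


@dataclass
class GGN:
    """Graphlet-guided network: union of significant graphlet matches.

    A subgraph of the reference interactome; every edge belongs to at
    least one match of a significant graphlet.
    """

    subgraph: Interactome
    significant_graphlets: frozenset = frozenset()

    @property
    def nodes(self) -> set[str]:
        return self.subgraph.nodes

    @property
    def edges(self) -> set[frozenset]:
        return self.subgraph.edges

    @property
    def n_nodes(self) -> int:
        return self.subgraph.n_nodes

    @property
    def n_edges(self) -> int:
        return self.subgraph.n_edges


# ---------------------------------------------------------------------------
# constrained counting
# ---------------------------------------------------------------------------

def _valid_intermediates(nodes, degs, seeds):
    """Nodes that may serve as intermediate so that all others are seeds.

    A position qualifies when it sits at a maximum-degree orbit of the
    induced pattern (the intermediate may itself be a seed).  Returns an
    empty list when the subset admits no valid assignment.
    """
    non_seeds = [n for n in nodes if n not in seeds]
    if len(non_seeds) > 1:
        return []
    max_deg = max(degs.values())
    if non_seeds:
        n = non_seeds[0]
        return [n] if degs[n] == max_deg else []
    return [n for n in nodes if degs[n] == max_deg]


def _enumerate_constrained(graph: Interactome, seeds: SeedSet):
    """Yield (graphlet_id, subset, intermediate, induced_edges) once per
    valid connected 2-4-node subset.

    Enumeration is ESU-style (each connected subset visited exactly once,
    rooted at its lowest-index node) with a seed prune: a growing subset
    may contain at most one non-seed, which keeps the search anchored to
    the seed neighbourhood and tractable on sparse interactomes.
    """
    g = graph.graph
    seed_nodes = seeds.nodes
    order_idx = {v: i for i, v in enumerate(sorted(g.nodes))}

    def emit(sub):
        nodes = frozenset(sub)
        degs = {}
        edges = []
        for a, b in combinations(sub, 2):
            if g.has_edge(a, b):
                edges.append(frozenset((a, b)))
                degs[a] = degs.get(a, 0) + 1
                degs[b] = degs.get(b, 0) + 1
        for n in sub:
            degs.setdefault(n, 0)
        order = len(sub)
        if order == 2:
            if all(n in seed_nodes for n in sub):
                return ("G0", nodes, None, frozenset(edges))
            return None
        inters = _valid_intermediates(sub, degs, seed_nodes)
        if not inters:
            return None
        gid = _classify(order, len(edges), max(degs.values()))
        # deterministic representative intermediate: the non-seed when
        # present, otherwise the smallest qualifying node id
        non_seeds = [n for n in sub if n not in seed_nodes]
        inter = non_seeds[0] if non_seeds else min(inters)
        return (gid, nodes, inter, frozenset(edges))

    def extend(sub, ext, nbrhood, root_i, n_nonseed):
        ext = list(ext)
        while ext:
            w = ext.pop()
            w_nonseed = n_nonseed + (0 if w in seed_nodes else 1)
            if w_nonseed > 1:
                continue
            new_sub = sub + [w]
            res = emit(new_sub)
            if res is not None:
                yield res
            if len(new_sub) < 4:
                new_ext = [u for u in ext]
                new_nbr = set(nbrhood)
                for u in g[w]:
                    if order_idx[u] > root_i and u not in new_nbr:
                        new_ext.append(u)
                        new_nbr.add(u)
                yield from extend(new_sub, new_ext, new_nbr, root_i, w_nonseed)

    for v in g.nodes:
        vi = order_idx[v]
        v_nonseed = 0 if v in seed_nodes else 1
        ext = [u for u in g[v] if order_idx[u] > vi]
        nbrhood = set(ext) | {v}
        yield from extend([v], ext, nbrhood, vi, v_nonseed)


def count_all_constrained(graph: Interactome, seeds: SeedSet,
                          collect_matches: bool = True):
    """Constrained counts for all nine graphlets in one enumeration pass.

    Returns (counts, matches) where counts maps graphlet id -> int and
    matches maps graphlet id -> list of :class:`GraphletMatch` (empty
    lists when ``collect_matches`` is false).
    """
    counts = {gid: 0 for gid in GRAPHLET_IDS}
    matches: dict[str, list[GraphletMatch]] = {gid: [] for gid in GRAPHLET_IDS}
    for gid, nodes, inter, edges in _enumerate_constrained(graph, seeds):
        counts[gid] += 1
        if collect_matches:
            matches[gid].append(
                GraphletMatch(graphlet=gid, nodes=nodes,
                              intermediate=inter, edges=edges)
            )
    return counts, matches


def count_constrained(graph: Interactome, seeds: SeedSet,
                      graphlet: GraphletType | str):
    """Count constrained occurrences of one graphlet type.

    Returns (count, matches).  A subset is counted once per graphlet type
    even when several intermediate assignments exist.
    """
    gid = graphlet if isinstance(graphlet, str) else graphlet.id
    counts, matches = count_all_constrained(graph, seeds)
    return counts[gid], matches[gid]


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------

def permute_network(graph: Interactome, swap_factor: float = 10.0,
                    rng_seed: int | np.random.Generator = 0) -> Interactome:
    """Degree-preserving randomization by double-edge swaps.

    Attempts ``ceil(swap_factor * |E|)`` swaps; each accepted swap
    replaces edges (a,b),(c,d) on four distinct nodes with (a,c),(b,d)
    (orientation of the second edge randomized, covering both rewirings)
    provided neither new edge already exists.  The new edge (a,c) carries
    the confidence of the displaced (a,b) and (b,d) that of (c,d), so the
    confidence multiset is preserved alongside the degree sequence.
    """
    if graph.n_edges < 2:
        logger.warning("graph has <2 edges; returning an identical copy")
        return graph.copy()
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    edges = [tuple(sorted(e)) for e in graph.graph.edges()]
    conf = {e: graph.graph[e[0]][e[1]]["confidence"] for e in edges}
    edge_set = set(edges)
    n_edges = len(edges)
    n_attempts = math.ceil(swap_factor * n_edges)

    idx = rng.integers(0, n_edges, size=(n_attempts, 2))
    flip = rng.integers(0, 2, size=n_attempts)
    accepted = 0
    for t in range(n_attempts):
        i, j = idx[t]
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if flip[t]:
            c, d = d, c
        if len({a, b, c, d}) < 4:
            continue
        e1 = (a, c) if a < c else (c, a)
        e2 = (b, d) if b < d else (d, b)
        if e1 in edge_set or e2 in edge_set:
            continue
        old1, old2 = edges[i], edges[j]
        edge_set.discard(old1)
        edge_set.discard(old2)
        edge_set.add(e1)
        edge_set.add(e2)
        edges[i], edges[j] = e1, e2
        c1, c2 = conf.pop(old1), conf.pop(old2)
        conf[e1], conf[e2] = c1, c2
        accepted += 1
    if accepted == 0:
        logger.warning("no legal double-edge swap found; returning a copy")
    return Interactome.from_edges([(u, v, conf[(u, v)]) for u, v in edges])


def graphlet_significance(graph: Interactome, seeds: SeedSet,
                          n_permutations: int = 100, alpha_z: float = 1.65,
                          swap_factor: float = 10.0,
                          rng_seed: int = 0) -> GraphletCensus:
    """Z-test of observed constrained counts against the permutation null.

    For each graphlet g: z = (observed - mean_perm) / sd_perm with the
    sample (ddof=1) standard deviation over ``n_permutations`` permuted
    networks; significant iff z > ``alpha_z`` (one-sided, default 1.65,
    i.e. P < 0.05).  With a degenerate null (sd = 0) the graphlet is
    significant iff the observed count exceeds every permuted count.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    observed, _ = count_all_constrained(graph, seeds, collect_matches=False)
    rng = np.random.default_rng(rng_seed)
    perm_counts: dict[str, list[int]] = {gid: [] for gid in GRAPHLET_IDS}
    for _ in range(n_permutations):
        perm = permute_network(graph, swap_factor=swap_factor, rng_seed=rng)
        counts, _ = count_all_constrained(perm, seeds, collect_matches=False)
        for gid in GRAPHLET_IDS:
            perm_counts[gid].append(counts[gid])
    z: dict[str, float] = {}
    significant: dict[str, bool] = {}
    for gid in GRAPHLET_IDS:
        obs = observed[gid]
        perm = perm_counts[gid]
        mean = float(np.mean(perm))
        sd = float(np.std(perm, ddof=1)) if len(perm) > 1 else 0.0
        if sd > 0:
            z[gid] = (obs - mean) / sd
            significant[gid] = z[gid] > alpha_z
        else:
            z[gid] = math.inf if obs > mean else (0.0 if obs == mean else -math.inf)
            significant[gid] = obs > max(perm)
    return GraphletCensus(observed=observed, perm_counts=perm_counts, z=z,
                          significant=significant, alpha_z=alpha_z)


def build_ggn(graph: Interactome, seeds: SeedSet, census: GraphletCensus,
              matches: dict[str, list[GraphletMatch]]) -> GGN:
    """Union of all matches of significant graphlets, as a subgraph of R."""
    sig = frozenset(g for g, ok in census.significant.items() if ok)
    if not sig:
        logger.warning("no graphlet is significant; GGN is empty")
        return GGN(subgraph=Interactome(), significant_graphlets=sig)
    edge_union: set[tuple] = set()
    node_union: set[str] = set()
    for gid in sig:
        for m in matches.get(gid, []):
            node_union |= m.nodes
            edge_union |= {tuple(sorted(e)) for e in m.edges}
    sub = graph.edge_subgraph(edge_union, extra_nodes=node_union)
    return GGN(subgraph=sub, significant_graphlets=sig)
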