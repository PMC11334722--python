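"""Desk-scale benchmark instances: scale-free interactomes with planted
pathways.

The generator emulates the situation the inference method is built for —
a genome-scale reference interactome with hub-dominated, power-law
degrees, a hidden context-specific pathway whose interactions carry
higher confidence, and a sparse omic readout (seeds) covering only part
of that pathway.  Annotation terms (one per planted pathway plus
degree-matched decoys) make the enrichment stage testable end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import networkx as nx
import numpy as np

from .evaluation import GoldStandard
from .io import AnnotationCollection, Interactome, SeedSet, ValidationError

__all__ = ["BenchmarkInstance", "generate_interactome", "plant_pathway"]


@dataclass
class BenchmarkInstance:
    """A generated interactome with planted, recoverable ground truth."""

    interactome: Interactome
    planted_pathway: GoldStandard
    seeds: SeedSet
    annotations: AnnotationCollection
    rng_seed: int
    params: dict[str, Any] = field(default_factory=dict)


def generate_interactome(n_nodes: int, attachment: int = 2,
                         confidence_dist: str = "uniform",
                         rng_seed: int = 0) -> Interactome:
    """Preferential-attachment (Barabási–Albert) interactome.

    Node ids are v0..v{n-1}; confidences are drawn per edge from the
    chosen distribution over (0, 1]: ``uniform`` on (0, 1], or ``beta``
    (Beta(4, 2), skewed toward high confidence as curated interactomes
    are).
    """
    if not (n_nodes > attachment >= 1):
        raise ValidationError(
            f"need n_nodes > attachment >= 1, got {n_nodes}, {attachment}"
        )
    rng = np.random.default_rng(rng_seed)
    g = nx.barabasi_albert_graph(n_nodes, attachment,
                                 seed=int(rng.integers(2**31)))
    if confidence_dist == "uniform":
        draw = lambda size: 1.0 - rng.random(size)  # (0, 1]
    elif confidence_dist == "beta":
        draw = lambda size: np.clip(rng.beta(4, 2, size), 1e-9, 1.0)
    else:
        raise ValidationError(f"unknown confidence_dist {confidence_dist!r}")
    edges = sorted(g.edges())
    confs = draw(len(edges))
    return Interactome.from_edges(
        (f"v{u}", f"v{v}", float(c)) for (u, v), c in zip(edges, confs)
    )


def _grow_connected_subset(graph: Interactome, size: int,
                           rng: np.random.Generator) -> list[str]:
    """Random BFS-style growth of a connected induced subgraph."""
    nodes = sorted(graph.nodes)
    for _ in range(50):  # restarts from different anchors
        start = nodes[rng.integers(len(nodes))]
        chosen = [start]
        chosen_set = {start}
        frontier = sorted(set(graph.neighbors(start)))
        while len(chosen) < size and frontier:
            nxt = frontier.pop(rng.integers(len(frontier)))
            chosen.append(nxt)
            chosen_set.add(nxt)
            for nb in graph.neighbors(nxt):
                if nb not in chosen_set and nb not in frontier:
                    frontier.append(nb)
            frontier.sort()
        if len(chosen) == size:
            return chosen
    raise ValidationError(
        f"could not grow a connected subgraph of size {size}"
    )


def plant_pathway(interactome: Interactome, pathway_size: int,
                  seed_fraction: float, rng_seed: int = 0,
                  confidence_boost: float = 0.5,
                  n_decoys: int = 5) -> BenchmarkInstance:
    """Plant a connected pathway and derive seeds, truth and annotations.

    The pathway is a connected induced subgraph of the requested size;
    its internal edge confidences are mixed toward 1 with weight
    ``confidence_boost`` (c' = c + boost·(1-c)), creating a recoverable
    signal without making recovery trivial.  ⌈seed_fraction·size⌉
    pathway nodes become seeds (weight 1).  Annotations contain one term
    for the pathway plus ``n_decoys`` degree-matched decoy terms drawn
    from non-pathway nodes, so enrichment cannot succeed by set size or
    hubness alone.
    """
    if pathway_size > interactome.n_nodes:
        raise ValidationError("pathway larger than the interactome")
    if not (0.0 < seed_fraction <= 1.0):
        raise ValidationError(f"seed_fraction {seed_fraction} outside (0, 1]")
    rng = np.random.default_rng(rng_seed)
    pathway = _grow_connected_subset(interactome, pathway_size, rng)
    pathway_set = set(pathway)

    g = interactome.graph.copy()
    truth_edges = set()
    for u, v, data in g.edges(data=True):
        if u in pathway_set and v in pathway_set:
            data["confidence"] = min(
                1.0, data["confidence"]
                + confidence_boost * (1.0 - data["confidence"]))
            truth_edges.add(frozenset((u, v)))
    boosted = Interactome(g)

    n_seeds = int(np.ceil(seed_fraction * pathway_size))
    seed_nodes = sorted(
        np.array(sorted(pathway_set))[rng.permutation(pathway_size)[:n_seeds]]
    )
    seeds = SeedSet.from_nodes(seed_nodes, boosted)

    truth = GoldStandard.from_interactome(pathway_set, truth_edges, boosted)

    sets = {"planted_pathway": ("planted pathway", frozenset(pathway_set))}
    # degree-matched decoys: for each pathway node, pick an unused
    # non-pathway node of the nearest degree
    outside = sorted(interactome.nodes - pathway_set)
    for d in range(n_decoys):
        shuffled = list(outside)
        rng.shuffle(shuffled)
        out_deg = np.array([interactome.degree(v) for v in shuffled])
        used: set[str] = set()
        members = []
        for node in sorted(pathway_set):
            target = interactome.degree(node)
            order = np.argsort(np.abs(out_deg - target), kind="stable")
            for j in order:
                cand = shuffled[j]
                if cand not in used:
                    members.append(cand)
                    used.add(cand)
                    break
        sets[f"decoy_{d}"] = (f"degree-matched decoy {d}",
                              frozenset(members))
    annotations = AnnotationCollection(sets=sets, universe=boosted.nodes)

    params = dict(pathway_size=pathway_size, seed_fraction=seed_fraction,
                  confidence_boost=confidence_boost, n_decoys=n_decoys)
    return BenchmarkInstance(interactome=boosted, planted_pathway=truth,
                             seeds=seeds, annotations=annotations,
                             rng_seed=rng_seed, params=params)
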