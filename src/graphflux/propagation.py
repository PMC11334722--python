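"""Personalized PageRank propagation, edge-flux scoring and τ-selection.

The random walker follows interactome edges with uniform probability over
a node's neighbours and teleports with probability (1 - λ) to a restart
distribution π — the normalized seed weights by default, or uniform over
all nodes.  The stationary probability p(v) measures proximity to the
seeds.  Each edge e = {u, t} then receives two directional fluxes

    f_{u→t} = p(u) · c(e) / deg(u)

combining propagation score, edge confidence and a hub-penalizing degree
normalization; the edge score is f(e) = -log(min of the two fluxes), and
edges are selected from the GGN in decreasing min-flux order until a
fraction τ of the total score mass F = Σ f(e) is spent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .graphlets import GGN, GraphletCensus, build_ggn, count_all_constrained, \
    graphlet_significance
from .io import Interactome, SeedSet, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "PropagationConfig",
    "PropagationResult",
    "EdgeScoreTable",
    "ContextNetwork",
    "personalized_pagerank",
    "compute_edge_flux",
    "select_edges",
    "infer",
]


@dataclass
class PropagationConfig:
    """Tunables of the PageRank iteration.

    damping: probability λ of following an edge (1-λ teleports).
    tolerance: L1 threshold on successive iterates declaring convergence.
    teleport_mode: "seeds" restarts at the weighted seeds (personalized);
    "uniform" restarts anywhere, the textbook PageRank form.
    """

    damping: float = 0.85
    tolerance: float = 1e-8
    max_iterations: int = 1000
    teleport_mode: str = "seeds"

    def __post_init__(self):
        if not (0.0 < self.damping < 1.0):
            raise ValidationError(f"damping {self.damping} outside (0, 1)")
        if self.tolerance <= 0:
            raise ValidationError("tolerance must be > 0")
        if self.max_iterations < 1:
            raise ValidationError("max_iterations must be >= 1")
        if self.teleport_mode not in ("seeds", "uniform"):
            raise ValidationError(
                f"teleport_mode {self.teleport_mode!r} not in {{seeds, uniform}}"
            )


@dataclass
class PropagationResult:
    """Stationary visit probabilities p(v); Σ p(v) = 1."""

    p: dict[str, float]
    iterations_used: int
    converged: bool

    def __getitem__(self, node: str) -> float:
        return self.p[node]


def personalized_pagerank(graph: Interactome, seeds: SeedSet,
                          config: PropagationConfig | None = None
                          ) -> PropagationResult:
    """Power iteration of p ← (1-λ)·π + λ·W·p.

    W is the column-degree-normalized adjacency operator (each node
    spreads its mass uniformly over its neighbours).  Mass sitting on
    dangling (degree-zero) nodes is redistributed to π each step, keeping
    Σ p = 1.
    """
    config = config or PropagationConfig()
    if len(seeds) == 0:
        raise ValidationError("empty seed set")
    nodes = sorted(graph.nodes)
    if not nodes:
        raise ValidationError("empty graph")
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)

    if config.teleport_mode == "uniform":
        pi = np.full(n, 1.0 / n)
    else:
        pi = np.zeros(n)
        total_w = sum(seeds.weights.values())
        for s, w in seeds.weights.items():
            if s in index:
                pi[index[s]] = w / total_w
        if pi.sum() == 0:
            raise ValidationError("no seed lies in the graph")
        pi /= pi.sum()

    deg = np.array([graph.degree(v) for v in nodes], dtype=float)
    rows, cols = [], []
    for u, v in graph.graph.edges():
        iu, iv = index[u], index[v]
        rows.extend((iu, iv))
        cols.extend((iv, iu))
    data = 1.0 / deg[cols] if rows else np.array([])
    W = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
    dangling = deg == 0

    lam = config.damping
    p = pi.copy()
    converged = False
    iterations = 0
    for iterations in range(1, config.max_iterations + 1):
        dangling_mass = p[dangling].sum() if dangling.any() else 0.0
        p_new = (1.0 - lam) * pi + lam * (W @ p + dangling_mass * pi)
        delta = np.abs(p_new - p).sum()
        p = p_new
        if delta < config.tolerance:
            converged = True
            break
    if not converged:
        logger.warning("PageRank did not converge in %d iterations",
                       config.max_iterations)
    return PropagationResult(
        p={v: float(p[index[v]]) for v in nodes},
        iterations_used=iterations, converged=converged,
    )


class EdgeScoreTable:
    """Per-edge directional fluxes, min-flux and score f(e) = -log(min).

    Backed by a DataFrame (columns node_a, node_b, flux_forward,
    flux_backward, min_flux, f_e); edges whose min-flux is zero carry an
    infinite score and are excluded from selection.
    """

    def __init__(self, frame: pd.DataFrame, log_base: float):
        self.frame = frame
        self.log_base = log_base
        self._by_edge = {
            frozenset((a, b)): (mf, fe)
            for a, b, mf, fe in zip(frame["node_a"], frame["node_b"],
                                    frame["min_flux"], frame["f_e"])
        }

    def min_flux(self, u: str, v: str) -> float:
        return self._by_edge[frozenset((u, v))][0]

    def score(self, u: str, v: str) -> float:
        return self._by_edge[frozenset((u, v))][1]

    def __contains__(self, edge) -> bool:
        return frozenset(edge) in self._by_edge

    def __len__(self) -> int:
        return len(self._by_edge)


def compute_edge_flux(graph: Interactome, propagation: PropagationResult,
                      log_base: float | str = 10) -> EdgeScoreTable:
    """Score every edge of ``graph`` from the propagation result.

    Degrees are taken in the graph the fluxes are computed on (the
    reference interactome in the standard pipeline).  f(e) uses log base
    10 by default; base e is accepted as ``"e"``.
    """
    base = math.e if log_base in ("e", math.e) else float(log_base)
    log_div = math.log(base)
    rows = []
    for u, v in sorted(map(sorted, graph.graph.edges())):
        c = graph.confidence(u, v)
        if c <= 0:
            raise ValidationError(f"edge ({u}, {v}) confidence {c} <= 0")
        fu = propagation.p[u] * c / graph.degree(u)
        fv = propagation.p[v] * c / graph.degree(v)
        mf = min(fu, fv)
        fe = -math.log(mf) / log_div if mf > 0 else math.inf
        rows.append((u, v, fu, fv, mf, fe))
    frame = pd.DataFrame(
        rows, columns=["node_a", "node_b", "flux_forward", "flux_backward",
                       "min_flux", "f_e"],
    )
    return EdgeScoreTable(frame, base)


@dataclass
class ContextNetwork:
    """The inferred context-specific network C, a subgraph of the GGN.

    Edge attributes: confidence, min_flux, f_e, selected_rank (1-based
    selection order).  ``total_flux`` is F = Σ f(e) over the finite-score
    GGN edges the τ budget was measured against.
    """

    graph: nx.Graph
    tau: float
    total_flux: float

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

    @property
    def selected_rank(self) -> dict[frozenset, int]:
        return {frozenset((u, v)): d["selected_rank"]
                for u, v, d in self.graph.edges(data=True)}


def select_edges(ggn: GGN, scores: EdgeScoreTable, tau: float,
                 literal_descending_score: bool = False) -> ContextNetwork:
    """Keep the best GGN edges up to a fraction τ of the score mass.

    Edges are ranked by descending min-flux (equivalently ascending
    f(e)): highest-confidence, highest-propagation edges first.  F sums
    f(e) over all finite-score GGN edges; edges are taken in rank order
    while the running sum stays below τ·F, including the edge that first
    reaches the budget (so τ=1 selects every finite-score edge and τ=0
    selects none).  ``literal_descending_score`` reverses the ranking to
    descending f(e) for the literal reading of the selection index
    convention; the default order matches the stated intent of keeping
    high-scoring edges.
    """
    if not (0.0 <= tau <= 1.0):
        raise ValidationError(f"tau {tau} outside [0, 1]")
    if ggn.n_edges == 0:
        logger.warning("empty GGN; context network is empty")
        return ContextNetwork(graph=nx.Graph(), tau=tau, total_flux=0.0)
    ranked = []
    for e in ggn.edges:
        u, v = sorted(e)
        if (u, v) not in scores and e not in scores:
            raise ValidationError(f"GGN edge ({u}, {v}) missing from scores")
        mf = scores.min_flux(u, v)
        fe = scores.score(u, v)
        if math.isinf(fe):
            continue  # zero-flux edges never enter the selection
        ranked.append((mf, fe, u, v))
    if literal_descending_score:
        ranked.sort(key=lambda r: (-r[1], r[2], r[3]))
    else:
        ranked.sort(key=lambda r: (-r[0], r[2], r[3]))
    total = sum(r[1] for r in ranked)
    budget = tau * total
    g = nx.Graph()
    cum = 0.0
    for rank, (mf, fe, u, v) in enumerate(ranked, start=1):
        if cum >= budget:
            break
        g.add_edge(u, v, confidence=ggn.subgraph.confidence(u, v),
                   min_flux=mf, f_e=fe, selected_rank=rank)
        cum += fe
    return ContextNetwork(graph=g, tau=tau, total_flux=total)


@dataclass
class InferenceArtifacts:
    """Everything the three-stage pipeline produces."""

    census: GraphletCensus
    matches: dict
    ggn: GGN
    propagation: PropagationResult
    scores: EdgeScoreTable
    network: ContextNetwork


def infer(graph: Interactome, seeds: SeedSet, *,
          tau: float = 0.5,
          propagation_config: PropagationConfig | None = None,
          n_permutations: int = 100, alpha_z: float = 1.65,
          swap_factor: float = 10.0, log_base: float | str = 10,
          literal_descending_score: bool = False,
          rng_seed: int = 0) -> InferenceArtifacts:
    """Run the full pipeline: GGN construction, flux scoring, selection.

    Deterministic for a fixed ``rng_seed``.  Fluxes are computed on the
    reference interactome (reference degrees) and then restricted to the
    GGN for selection, so trimming never changes an edge's score.
    """
    census = graphlet_significance(
        graph, seeds, n_permutations=n_permutations, alpha_z=alpha_z,
        swap_factor=swap_factor, rng_seed=rng_seed,
    )
    _, matches = count_all_constrained(graph, seeds)
    ggn = build_ggn(graph, seeds, census, matches)
    propagation = personalized_pagerank(graph, seeds, propagation_config)
    scores = compute_edge_flux(graph, propagation, log_base=log_base)
    network = select_edges(ggn, scores, tau,
                           literal_descending_score=literal_descending_score)
    return InferenceArtifacts(census=census, matches=matches, ggn=ggn,
                              propagation=propagation, scores=scores,
                              network=network)
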