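"""Scoring inferred networks against gold standards.

Node and edge recovery are summarized by the area under the
precision-recall curve (ranking all universe items by their propagation
or flux score) and by point precision/recall/F1 at the selected network.
Hub trimming is quantified by per-hub reduction ratios, and the
scale-free character of a network by a log-log power-law fit to its
degree histogram.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score

from .graphlets import GGN
from .io import Interactome, ValidationError
from .propagation import ContextNetwork, EdgeScoreTable, PropagationResult

__all__ = [
    "GoldStandard",
    "EvaluationReport",
    "HubReport",
    "PowerLawFit",
    "evaluate_recovery",
    "hub_reduction",
    "fit_power_law",
    "cross_validate_seeds",
]


@dataclass
class GoldStandard:
    """True pathway nodes/edges plus the negatives' domain.

    Universe defaults to the reference interactome: negatives are all
    reference nodes/edges outside the truth.
    """

    true_nodes: set[str]
    true_edges: set[frozenset]
    universe_nodes: set[str]
    universe_edges: set[frozenset]

    def __post_init__(self):
        self.true_edges = {frozenset(e) for e in self.true_edges}
        self.universe_edges = {frozenset(e) for e in self.universe_edges}
        if not self.true_nodes <= self.universe_nodes:
            raise ValidationError("true nodes not contained in universe")
        if not self.true_edges <= self.universe_edges:
            raise ValidationError("true edges not contained in universe")

    @classmethod
    def from_interactome(cls, truth_nodes, truth_edges,
                         interactome: Interactome) -> "GoldStandard":
        return cls(true_nodes=set(truth_nodes),
                   true_edges={frozenset(e) for e in truth_edges},
                   universe_nodes=interactome.nodes,
                   universe_edges=interactome.edges)


def _f1(p: float, r: float) -> float:
    return 2 * p * r / (p + r) if (p + r) > 0 else 0.0


@dataclass
class EvaluationReport:
    node_auprc: float
    edge_auprc: float
    node_precision: float
    node_recall: float
    node_f1: float
    edge_precision: float
    edge_recall: float
    edge_f1: float
    positives_ratio: float

    # headline point metrics (edge-level, matching the network's purpose)
    @property
    def precision(self) -> float:
        return self.edge_precision

    @property
    def recall(self) -> float:
        return self.edge_recall

    def to_dict(self) -> dict:
        return {
            "node_auprc": self.node_auprc, "edge_auprc": self.edge_auprc,
            "node_precision": self.node_precision,
            "node_recall": self.node_recall, "node_f1": self.node_f1,
            "edge_precision": self.edge_precision,
            "edge_recall": self.edge_recall, "edge_f1": self.edge_f1,
            "positives_ratio": self.positives_ratio,
        }


def _auprc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Step-wise (interpolation-free) area under precision-recall."""
    if labels.sum() == 0:
        raise ValidationError("no positives in the universe")
    return float(average_precision_score(labels, scores))


def evaluate_recovery(predicted: ContextNetwork, truth: GoldStandard,
                      scores: EdgeScoreTable | None = None,
                      node_scores: PropagationResult | dict | None = None
                      ) -> EvaluationReport:
    """Point precision/recall/F1 at the network plus ranking AUPRCs.

    Edge ranking uses min-flux (descending) over the universe edges;
    node ranking uses the propagation probabilities.  Universe items
    without a score rank at the bottom (score 0).
    """
    if not truth.true_nodes and not truth.true_edges:
        raise ValidationError("empty gold standard")
    pred_nodes = predicted.nodes & truth.universe_nodes
    pred_edges = predicted.edges & truth.universe_edges

    tp_n = len(pred_nodes & truth.true_nodes)
    node_p = tp_n / len(pred_nodes) if pred_nodes else 0.0
    node_r = tp_n / len(truth.true_nodes) if truth.true_nodes else 0.0
    tp_e = len(pred_edges & truth.true_edges)
    edge_p = tp_e / len(pred_edges) if pred_edges else 0.0
    edge_r = tp_e / len(truth.true_edges) if truth.true_edges else 0.0

    node_auprc = float("nan")
    if node_scores is not None and truth.true_nodes:
        pmap = node_scores.p if isinstance(node_scores, PropagationResult) \
            else dict(node_scores)
        universe = sorted(truth.universe_nodes)
        y = np.array([v in truth.true_nodes for v in universe], dtype=float)
        s = np.array([pmap.get(v, 0.0) for v in universe])
        node_auprc = _auprc(y, s)

    edge_auprc = float("nan")
    if scores is not None and truth.true_edges:
        universe_e = sorted(tuple(sorted(e)) for e in truth.universe_edges)
        y = np.array([frozenset(e) in truth.true_edges for e in universe_e],
                     dtype=float)
        s = np.array([scores.min_flux(*e) if e in scores else 0.0
                      for e in universe_e])
        edge_auprc = _auprc(y, s)

    n_pos = len(truth.true_edges) if truth.true_edges else len(truth.true_nodes)
    n_all = len(truth.universe_edges) if truth.true_edges \
        else len(truth.universe_nodes)
    n_neg = n_all - n_pos
    return EvaluationReport(
        node_auprc=node_auprc, edge_auprc=edge_auprc,
        node_precision=node_p, node_recall=node_r, node_f1=_f1(node_p, node_r),
        edge_precision=edge_p, edge_recall=edge_r, edge_f1=_f1(edge_p, edge_r),
        positives_ratio=n_pos / n_neg if n_neg else math.inf,
    )


@dataclass
class HubReport:
    """Hubs (top degree quantile in the reference) and their trimming."""

    hubs: set[str]
    reduction_ratio: dict[str, float]

    @property
    def mean_reduction(self) -> float:
        return float(np.mean(list(self.reduction_ratio.values())))

    @property
    def n_removed(self) -> int:
        return sum(1 for r in self.reduction_ratio.values() if r == 1.0)


def hub_reduction(reference: Interactome, trimmed, quantile: float = 0.2
                  ) -> HubReport:
    """Reduction ratio RR(h) = 1 - deg_trimmed(h)/deg_reference(h).

    Hubs are the ⌈quantile·|V|⌉ highest-degree reference nodes (top 20%
    by default; degree ties broken by node id for determinism).  A hub
    absent from the trimmed network has RR = 1.
    """
    if not (0.0 < quantile <= 1.0):
        raise ValidationError(f"quantile {quantile} outside (0, 1]")
    tg = trimmed.subgraph.graph if isinstance(trimmed, GGN) else trimmed.graph
    n_hubs = math.ceil(quantile * reference.n_nodes)
    by_degree = sorted(reference.nodes,
                       key=lambda v: (-reference.degree(v), v))
    hubs = set(by_degree[:n_hubs])
    rr = {}
    for h in hubs:
        d_ref = reference.degree(h)
        d_trim = tg.degree(h) if h in tg else 0
        rr[h] = 1.0 - d_trim / d_ref if d_ref else 0.0
    return HubReport(hubs=hubs, reduction_ratio=rr)


@dataclass
class PowerLawFit:
    """Degree exponent γ and R² from the log10-log10 histogram line."""

    gamma: float
    r_squared: float
    n_degrees: int


def fit_power_law(graph) -> PowerLawFit:
    """Least squares on (log10 k, log10 N(k)) over non-empty degree bins.

    γ is minus the slope; a pure N(k) ∝ k^-γ histogram is recovered
    exactly.  Needs at least three distinct positive degrees.
    """
    if isinstance(graph, GGN):
        g = graph.subgraph.graph
    elif isinstance(graph, Interactome):
        g = graph.graph
    else:
        g = graph
    degrees = [d for _, d in g.degree() if d > 0]
    ks, counts = np.unique(degrees, return_counts=True)
    if len(ks) < 3:
        raise ValidationError(
            f"need >=3 distinct degrees for a power-law fit, got {len(ks)}"
        )
    x = np.log10(ks.astype(float))
    y = np.log10(counts.astype(float))
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return PowerLawFit(gamma=float(-slope), r_squared=r2, n_degrees=len(ks))


def cross_validate_seeds(graph: Interactome, seeds, n_folds: int = 5,
                         rng_seed: int = 0, **infer_kwargs):
    """k-fold seed-holdout: infer from the retained seeds, score recovery
    of the masked fold as truth nodes.

    Returns one EvaluationReport per fold.
    """
    from .io import SeedSet
    from .propagation import infer

    seed_nodes = sorted(seeds.nodes)
    if len(seed_nodes) < n_folds:
        raise ValidationError("fewer seeds than folds")
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(len(seed_nodes))
    folds = [sorted(seed_nodes[i] for i in order[f::n_folds])
             for f in range(n_folds)]
    reports = []
    for f, held_out in enumerate(folds):
        kept = {n: w for n, w in seeds.weights.items() if n not in held_out}
        art = infer(graph, SeedSet(weights=kept), rng_seed=rng_seed + f,
                    **infer_kwargs)
        truth = GoldStandard(true_nodes=set(held_out), true_edges=set(),
                             universe_nodes=graph.nodes,
                             universe_edges=graph.edges)
        reports.append(evaluate_recovery(art.network, truth,
                                         node_scores=art.propagation))
    return reports
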