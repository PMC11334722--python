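"""Module detection, hypergeometric enrichment and profile similarity.

An inferred network is partitioned into communities (modules) with the
Louvain algorithm; each module is tested for over-representation of each
annotation term with the exact hypergeometric upper tail, adjusted with
Benjamini-Hochberg FDR across all module-term pairs.  Networks from
different contexts (e.g. patients) are compared by cosine similarity of
their enrichment profiles over a shared term vocabulary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import AnnotationCollection, ValidationError
from .propagation import ContextNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "ModulePartition",
    "EnrichmentResult",
    "EnrichmentProfile",
    "detect_modules",
    "enrich_modules",
    "build_profile",
    "profile_similarity",
    "similarity_matrix",
    "cluster_profiles",
]


@dataclass
class ModulePartition:
    """Node -> module id assignment covering every network node."""

    assignment: dict[str, int]
    resolution: float
    rng_seed: int

    @property
    def modules(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for node, mod in self.assignment.items():
            out.setdefault(mod, set()).add(node)
        return out

    @property
    def n_modules(self) -> int:
        return len(set(self.assignment.values()))


def detect_modules(network: ContextNetwork | nx.Graph, resolution: float = 1.0,
                   rng_seed: int = 0) -> ModulePartition:
    """Louvain modularity maximization on the network topology.

    Deterministic given ``rng_seed``; nodes in singleton components end
    up in singleton modules.
    """
    g = network.graph if isinstance(network, ContextNetwork) else network
    if g.number_of_nodes() == 0:
        raise ValidationError("cannot partition an empty network")
    communities = nx.community.louvain_communities(
        g, weight=None, resolution=resolution, seed=rng_seed,
    )
    # stable module ids: order communities by their smallest member
    communities = sorted(communities, key=lambda c: min(c))
    assignment = {node: i for i, comm in enumerate(communities) for node in comm}
    return ModulePartition(assignment=assignment, resolution=resolution,
                           rng_seed=rng_seed)


@dataclass
class EnrichmentResult:
    """Hypergeometric enrichment rows, one per (module, term) pair."""

    frame: pd.DataFrame  # module, term, k, n, K, M, p_value, adjusted_p, significant
    fdr_alpha: float
    universe_size: int

    def significant_terms(self) -> set[str]:
        sig = self.frame[self.frame["significant"]]
        return set(sig["term"])


def hypergeometric_tail(k: int, M: int, K: int, n: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(M, K, n) — exact upper tail."""
    return float(hypergeom.sf(k - 1, M, K, n))


def enrich_modules(partition: ModulePartition,
                   annotations: AnnotationCollection,
                   universe_mode: str = "annotated",
                   fdr_alpha: float = 0.05,
                   reference_nodes: set[str] | None = None) -> EnrichmentResult:
    """Test every module against every term with the hypergeometric test.

    Universe M: in ``annotated`` mode, the nodes appearing in at least
    one annotation set (restricted to ``reference_nodes`` when given) —
    unannotated nodes can never contribute to an overlap and would
    otherwise deflate p-values; ``interactome`` mode uses all
    ``reference_nodes`` for comparability.  P-values are BH-adjusted
    across all module-term pairs; significant means adjusted p < alpha.
    """
    if universe_mode not in ("annotated", "interactome"):
        raise ValidationError(f"unknown universe_mode {universe_mode!r}")
    if annotations.universe is not None:
        universe = set(annotations.universe)
    elif universe_mode == "interactome":
        if reference_nodes is None:
            raise ValidationError(
                "universe_mode='interactome' needs reference_nodes"
            )
        universe = set(reference_nodes)
    else:
        universe = annotations.annotated_nodes
        if reference_nodes is not None:
            universe &= set(reference_nodes)
    if not universe:
        logger.warning("annotation vocabulary disjoint from universe")
        empty = pd.DataFrame(columns=["module", "term", "k", "n", "K", "M",
                                      "p_value", "adjusted_p", "significant"])
        return EnrichmentResult(frame=empty, fdr_alpha=fdr_alpha,
                                universe_size=0)
    M = len(universe)
    rows = []
    for mod, members in sorted(partition.modules.items()):
        mod_in = members & universe
        n = len(mod_in)
        for term in sorted(annotations.sets):
            term_in = annotations.members(term) & universe
            K = len(term_in)
            k = len(mod_in & term_in)
            p = hypergeometric_tail(k, M, K, n) if K and n else 1.0
            rows.append((mod, term, k, n, K, M, p))
    frame = pd.DataFrame(rows, columns=["module", "term", "k", "n", "K", "M",
                                        "p_value"])
    if len(frame):
        reject, p_adj, _, _ = multipletests(frame["p_value"], alpha=fdr_alpha,
                                            method="fdr_bh")
        frame["adjusted_p"] = p_adj
        frame["significant"] = reject
    else:
        frame["adjusted_p"] = []
        frame["significant"] = []
    return EnrichmentResult(frame=frame, fdr_alpha=fdr_alpha, universe_size=M)


@dataclass
class EnrichmentProfile:
    """Vector over a fixed term vocabulary summarizing one network.

    Binary mode: 1 where the term is significant in at least one module.
    Weighted mode: -log10 of the best adjusted p across modules.
    """

    vocabulary: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.vocabulary) != len(self.values):
            raise ValidationError("profile length mismatch with vocabulary")
        if (self.values < 0).any():
            raise ValidationError("profile entries must be non-negative")


def build_profile(enrichment: EnrichmentResult, vocabulary: tuple[str, ...],
                  mode: str = "binary") -> EnrichmentProfile:
    if mode not in ("binary", "weighted"):
        raise ValidationError(f"unknown profile mode {mode!r}")
    values = np.zeros(len(vocabulary))
    frame = enrichment.frame
    for i, term in enumerate(vocabulary):
        rows = frame[frame["term"] == term]
        if not len(rows):
            continue
        if mode == "binary":
            values[i] = 1.0 if rows["significant"].any() else 0.0
        else:
            best = rows["adjusted_p"].min()
            values[i] = -np.log10(max(best, 1e-300))
    return EnrichmentProfile(vocabulary=tuple(vocabulary), values=values)


def profile_similarity(a: EnrichmentProfile, b: EnrichmentProfile) -> float:
    """Cosine similarity in [0, 1]; zero when either profile is all-zero."""
    if a.vocabulary != b.vocabulary:
        raise ValidationError("profiles use different term vocabularies")
    na, nb = np.linalg.norm(a.values), np.linalg.norm(b.values)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a.values, b.values) / (na * nb))


def similarity_matrix(profiles: dict[str, EnrichmentProfile]) -> pd.DataFrame:
    """Square cosine-similarity matrix across labelled profiles."""
    labels = sorted(profiles)
    mat = np.eye(len(labels))
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            s = profile_similarity(profiles[a], profiles[labels[j]])
            mat[i, j] = mat[j, i] = s
    return pd.DataFrame(mat, index=labels, columns=labels)


def cluster_profiles(similarity: pd.DataFrame, n_clusters: int = 4
                     ) -> dict[str, int]:
    """Average-linkage hierarchical clustering on 1 - similarity.

    Offered as a convenience for stratifying contexts by their
    enrichment profiles; the linkage and cut are a package choice, not
    part of the inference method.
    """
    dist = 1.0 - similarity.values
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(z, t=n_clusters, criterion="maxclust")
    return {name: int(lab) for name, lab in zip(similarity.index, labels)}
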