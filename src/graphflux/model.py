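"""Model/Results front end for context-specific network inference.

`ContextNetworkModel` holds the data (reference interactome + seeds) and
the method's tunables; `fit()` runs the three-stage pipeline — graphlet
census and GGN trimming, Personalized-PageRank flux scoring,
τ-selection — and returns an `InferenceResults` carrying every
intermediate artifact, diagnostics and a `summary()` table.  Module
detection, enrichment, evaluation and plotting hang off the results
object.

Example
-------
>>> from graphflux import synthetic
>>> from graphflux.model import ContextNetworkModel
>>> inst = synthetic.plant_pathway(
...     synthetic.generate_interactome(300, 2, rng_seed=1), 20, 0.5, rng_seed=1)
>>> res = ContextNetworkModel(inst.interactome, inst.seeds, tau=0.5).fit(rng_seed=1)
>>> res.network.n_edges <= res.ggn.n_edges  # C ⊆ G ⊆ R
True
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Any

import numpy as np

from . import __version__ as _pkg_version
from .evaluation import (EvaluationReport, GoldStandard, HubReport,
                         PowerLawFit, evaluate_recovery, fit_power_law,
                         hub_reduction)
from .io import (AnnotationCollection, Interactome, SeedSet, atomic_write,
                 load_interactome, load_seeds, write_interactome,
                 write_network)
from .modules import (EnrichmentResult, ModulePartition, detect_modules,
                      enrich_modules)
from .propagation import (ContextNetwork, EdgeScoreTable, InferenceArtifacts,
                          PropagationConfig, infer)

__all__ = ["ContextNetworkModel", "InferenceResults"]


class ContextNetworkModel:
    """Infers a context-specific network from an interactome and seeds.

    Parameters
    ----------
    interactome : Interactome
        Reference network R(V, E, c(e)) with confidences in (0, 1].
    seeds : SeedSet
        Omic hits with positive weights; the context signal.
    tau : float
        Fraction of the GGN flux-score mass retained (default 0.5).
    damping : float
        PageRank damping λ (default 0.85).
    n_permutations, alpha_z, swap_factor
        Permutation-null settings for the graphlet z-test (defaults 100,
        1.65, 10).
    log_base : {10, "e"}
        Base of the -log edge score.
    teleport_mode : {"seeds", "uniform"}
        Personalized restart at the seeds (default) or uniform restart.
    """

    def __init__(self, interactome: Interactome, seeds: SeedSet, *,
                 tau: float = 0.5, damping: float = 0.85,
                 tolerance: float = 1e-8, max_iterations: int = 1000,
                 n_permutations: int = 100, alpha_z: float = 1.65,
                 swap_factor: float = 10.0, log_base: float | str = 10,
                 teleport_mode: str = "seeds",
                 literal_descending_score: bool = False):
        self.interactome = interactome
        self.seeds = seeds
        self.tau = tau
        self.propagation_config = PropagationConfig(
            damping=damping, tolerance=tolerance,
            max_iterations=max_iterations, teleport_mode=teleport_mode,
        )
        self.n_permutations = n_permutations
        self.alpha_z = alpha_z
        self.swap_factor = swap_factor
        self.log_base = log_base
        self.literal_descending_score = literal_descending_score

    @classmethod
    def from_files(cls, network_path: str, seeds_path: str,
                   default_confidence: float = 1.0, **kwargs
                   ) -> "ContextNetworkModel":
        interactome = load_interactome(network_path, default_confidence)
        seeds = load_seeds(seeds_path, interactome)
        return cls(interactome, seeds, **kwargs)

    def params_dict(self) -> dict[str, Any]:
        return dict(tau=self.tau,
                    damping=self.propagation_config.damping,
                    tolerance=self.propagation_config.tolerance,
                    max_iterations=self.propagation_config.max_iterations,
                    teleport_mode=self.propagation_config.teleport_mode,
                    n_permutations=self.n_permutations,
                    alpha_z=self.alpha_z, swap_factor=self.swap_factor,
                    log_base=str(self.log_base),
                    literal_descending_score=self.literal_descending_score)

    def fit(self, rng_seed: int = 0) -> "InferenceResults":
        """Run census → GGN → propagation → flux → selection."""
        artifacts = infer(
            self.interactome, self.seeds, tau=self.tau,
            propagation_config=self.propagation_config,
            n_permutations=self.n_permutations, alpha_z=self.alpha_z,
            swap_factor=self.swap_factor, log_base=self.log_base,
            literal_descending_score=self.literal_descending_score,
            rng_seed=rng_seed,
        )
        return InferenceResults(model=self, artifacts=artifacts,
                                rng_seed=rng_seed)


class InferenceResults:
    """Fitted results: the GGN, edge scores, selected network, diagnostics."""

    def __init__(self, model: ContextNetworkModel,
                 artifacts: InferenceArtifacts, rng_seed: int):
        self.model = model
        self.rng_seed = rng_seed
        self.census = artifacts.census
        self.matches = artifacts.matches
        self.ggn = artifacts.ggn
        self.propagation = artifacts.propagation
        self.scores = artifacts.scores
        self.network = artifacts.network

    # -- downstream analyses --------------------------------------------
    def detect_modules(self, resolution: float = 1.0,
                       rng_seed: int | None = None) -> ModulePartition:
        seed = self.rng_seed if rng_seed is None else rng_seed
        return detect_modules(self.network, resolution=resolution,
                              rng_seed=seed)

    def enrich(self, annotations: AnnotationCollection,
               partition: ModulePartition | None = None,
               universe_mode: str = "annotated",
               fdr_alpha: float = 0.05) -> EnrichmentResult:
        partition = partition or self.detect_modules()
        return enrich_modules(partition, annotations,
                              universe_mode=universe_mode,
                              fdr_alpha=fdr_alpha,
                              reference_nodes=self.model.interactome.nodes)

    def evaluate(self, truth: GoldStandard) -> EvaluationReport:
        return evaluate_recovery(self.network, truth, scores=self.scores,
                                 node_scores=self.propagation)

    def hub_report(self, quantile: float = 0.2, against: str = "ggn"
                   ) -> HubReport:
        trimmed = self.ggn if against == "ggn" else self.network
        return hub_reduction(self.model.interactome, trimmed,
                             quantile=quantile)

    def power_law(self, which: str = "ggn") -> PowerLawFit:
        target = {"reference": self.model.interactome, "ggn": self.ggn,
                  "network": self.network}[which]
        return fit_power_law(target)

    # -- reporting -------------------------------------------------------
    def summary(self) -> str:
        m = self.model
        lines = [
            "Context-specific network inference",
            "=" * 50,
            f"Reference interactome: {m.interactome.n_nodes} nodes, "
            f"{m.interactome.n_edges} edges",
            f"Seeds: {len(m.seeds)} (coverage {m.seeds.coverage:.2f})",
            f"Parameters: tau={m.tau}, damping="
            f"{m.propagation_config.damping}, "
            f"teleport={m.propagation_config.teleport_mode}, "
            f"n_perm={m.n_permutations}, alpha_z={m.alpha_z}, "
            f"rng_seed={self.rng_seed}",
            "",
            "Graphlet census (observed vs permutation null)",
            "-" * 50,
            f"{'graphlet':>8} {'observed':>9} {'perm_mean':>10} "
            f"{'perm_sd':>9} {'z':>9}  sig",
        ]
        for row in self.census.to_rows():
            lines.append(
                f"{row['graphlet']:>8} {row['observed']:>9d} "
                f"{row['perm_mean']:>10.2f} {row['perm_sd']:>9.2f} "
                f"{row['z']:>9.2f}  {'*' if row['significant'] else ''}"
            )
        lines += [
            "-" * 50,
            f"GGN: {self.ggn.n_nodes} nodes, {self.ggn.n_edges} edges "
            f"(significant: "
            f"{', '.join(sorted(self.ggn.significant_graphlets)) or 'none'})",
            f"Propagation: {self.propagation.iterations_used} iterations, "
            f"converged={self.propagation.converged}",
            f"Context network: {self.network.n_nodes} nodes, "
            f"{self.network.n_edges} edges "
            f"(tau={self.network.tau}, F={self.network.total_flux:.4g})",
        ]
        return "\n".join(lines)

    def plot_degree_distributions(self, ax=None):
        """Log-log degree histograms of reference, GGN and network."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for label, net in [("reference", self.model.interactome.graph),
                           ("GGN", self.ggn.subgraph.graph),
                           ("network", self.network.graph)]:
            degs = [d for _, d in net.degree() if d > 0]
            if not degs:
                continue
            ks, counts = np.unique(degs, return_counts=True)
            ax.loglog(ks, counts, "o-", label=label, alpha=0.7)
        ax.set_xlabel("degree k")
        ax.set_ylabel("N(k)")
        ax.legend()
        return ax

    def to_dir(self, out_dir: str) -> None:
        """Write ggn.tsv, edge_scores.tsv, network.tsv, census.tsv and
        run_meta.json (enough to re-execute the run exactly)."""
        import os

        os.makedirs(out_dir, exist_ok=True)
        write_interactome(self.ggn.subgraph, os.path.join(out_dir, "ggn.tsv"))
        self.scores.frame.to_csv(os.path.join(out_dir, "edge_scores.tsv"),
                                 sep="\t", index=False)
        write_network(self.network, os.path.join(out_dir, "network.tsv"))
        census_rows = ["graphlet\tobserved\tperm_mean\tperm_sd\tz\tsignificant"]
        for row in self.census.to_rows():
            census_rows.append(
                f"{row['graphlet']}\t{row['observed']}\t{row['perm_mean']:.6g}"
                f"\t{row['perm_sd']:.6g}\t{row['z']:.6g}\t{row['significant']}"
            )
        atomic_write(os.path.join(out_dir, "census.tsv"),
                     "\n".join(census_rows) + "\n")
        meta = dict(package="graphflux", version=_pkg_version,
                    rng_seed=self.rng_seed, params=self.model.params_dict(),
                    n_seeds=len(self.model.seeds),
                    seed_coverage=self.model.seeds.coverage,
                    reference_nodes=self.model.interactome.n_nodes,
                    reference_edges=self.model.interactome.n_edges,
                    ggn_nodes=self.ggn.n_nodes, ggn_edges=self.ggn.n_edges,
                    network_nodes=self.network.n_nodes,
                    network_edges=self.network.n_edges,
                    total_flux=self.network.total_flux,
                    converged=self.propagation.converged)
        atomic_write(os.path.join(out_dir, "run_meta.json"),
                     json.dumps(meta, indent=2, sort_keys=True) + "\n")
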