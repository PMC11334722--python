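# graphflux

Context-specific network inference on protein–protein interactomes.

Genome-scale reference interactomes aggregate interactions across every
tissue, cell type and condition, so propagating a sparse set of omic hits
(phosphoproteins, driver genes, differentially expressed proteins) through
them tends to pull in nonspecific interactions — above all through hub
proteins, which connect everything to everything. `graphflux` infers a
context-specific subnetwork in three stages:

1. **Graphlet-guided trimming.** The nine connected non-isomorphic
   graphlets on 2–4 nodes (G0–G8) are searched in the reference network
   R(V, E, c(e)) under a seed constraint: one node in a maximum-degree
   orbit acts as the *intermediate* and every other node must be a seed.
   Observed counts are compared against counts on degree-preserving
   permuted networks (double-edge swaps) with a one-sided z-test
   (z > 1.65, i.e. P < 0.05, over 100 permutations by default). The union
   of all occurrences of significantly frequent graphlets forms the
   graphlet-guided network G ⊆ R.
2. **Personalized-PageRank flux scoring.** A random walker restarts at
   the weighted seeds with probability 1 − λ (λ = 0.85) and otherwise
   steps to a uniform neighbour; its stationary probability p(v) measures
   proximity to the seeds. Each edge e = {u, t} gets two directional
   fluxes f_{u→t} = p(u)·c(e)/deg(u) — propagation score times edge
   confidence, divided by degree so that hubs are penalized — and the
   edge score f(e) = −log₁₀ min(f_{u→t}, f_{t→u}).
3. **τ-selection.** Edges of G are ranked by descending min-flux and
   selected until a fraction τ (default 0.5) of the total score mass
   F = Σ f(e) is spent, giving the context network C ⊆ G ⊆ R.

Downstream, Louvain community detection splits C into modules, each
tested for annotation over-representation with the exact hypergeometric
tail (BH-adjusted), and networks from different contexts can be compared
by cosine similarity of their enrichment profiles.

## Worked example

The package ships a benchmark generator (no downloads needed): a
scale-free interactome with a planted 25-node pathway whose internal
edges carry boosted confidences, and seeds covering 40% of the pathway.

```python
import graphflux as gf
from graphflux.model import ContextNetworkModel

inter = gf.synthetic.generate_interactome(500, 2, rng_seed=11)
inst = gf.synthetic.plant_pathway(inter, 25, 0.4, rng_seed=11)

res = ContextNetworkModel(inst.interactome, inst.seeds, tau=0.5).fit(rng_seed=11)
print(res.summary())
```

```
Context-specific network inference
==================================================
Reference interactome: 500 nodes, 996 edges
Seeds: 10 (coverage 1.00)
Parameters: tau=0.5, damping=0.85, teleport=seeds, n_perm=100, alpha_z=1.65, rng_seed=11

Graphlet census (observed vs permutation null)
--------------------------------------------------
graphlet  observed  perm_mean   perm_sd         z  sig
      G0         2       0.35      0.54      3.06  *
      G1        24       3.19      2.48      8.39  *
      G2         0       0.01      0.10     -0.10
      G3         1       0.23      0.58      1.32
      G4        35       0.70      1.67     20.58  *
      G5         0       0.00      0.00      0.00
      G6         0       0.01      0.10     -0.10
      G7         0       0.00      0.00      0.00
      G8         0       0.00      0.00      0.00
--------------------------------------------------
GGN: 13 nodes, 13 edges (significant: G0, G1, G4)
Propagation: 53 iterations, converged=True
Context network: 10 nodes, 8 edges (tau=0.5, F=41.35)
```

The seed-dense region produces far more seed-covering paths (G1) and
stars (G4) than any degree-matched random rewiring, so those graphlets
are significant and the GGN collapses 996 reference edges to 13
candidates around the seeds. Scoring and τ-selection keep the 8
highest-flux edges. Against the planted truth:

```python
rep = res.evaluate(inst.planted_pathway)
hub = res.hub_report()
```

```
edge precision 1.000  edge recall 0.308  node AUPRC 0.625  edge AUPRC 0.376
mean hub reduction ratio 0.987 over 100 hubs
```

Every selected edge is a true pathway edge (precision 1.0) at ~31%
recall of the planted edges, and the top-20% highest-degree reference
nodes lose on average 98.7% of their interactions in the trimmed
network — the hub-suppression the degree normalization is designed for.

The same pipeline is available from the shell:

```sh
graphflux simulate --n-nodes 500 --pathway-size 25 --seed-fraction 0.4 \
    --rng-seed 11 --out sim/
graphflux infer --network sim/interactome.tsv --seeds sim/seeds.tsv \
    --tau 0.5 --rng-seed 11 --out run/
graphflux modules --network run/network.tsv --gmt sim/sets.gmt --out mod/
graphflux evaluate --network run/network.tsv --truth-nodes sim/truth_nodes.txt \
    --truth-edges sim/truth_edges.tsv --universe sim/interactome.tsv \
    --out report.json
```

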