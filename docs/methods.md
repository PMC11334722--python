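# Methods

## The model

`graphflux` treats context-specific network inference as a two-filter
problem on a reference interactome R(V, E, c(e)) with per-edge
confidences in (0, 1]: a *topological* filter that keeps only the region
of R whose local wiring around the seed nodes is unexpectedly dense, and
a *propagation* filter that ranks the surviving interactions by how much
random-walk probability mass they carry from the seeds.

### Seed-constrained graphlet census

Graphlets are the nine connected non-isomorphic undirected graphs on 2–4
nodes, numbered G0 (single edge), G1 (3-path), G2 (triangle), G3
(4-path), G4 (3-star), G5 (4-cycle), G6 (triangle + pendant), G7
(diamond) and G8 (4-clique). An occurrence is an *induced* subgraph
isomorphic to the pattern — a triangle's node set never counts as a
3-path. The seed constraint: one node sitting at a maximum-degree orbit
of the pattern is the intermediate, and every other node must be a seed;
G0 requires both endpoints to be seeds. The intermediate may itself be a
seed — the constraint demands seeds in the non-intermediate positions,
not a non-seed in the middle, which maximizes recall in seed-dense
regions. When a pattern's maximum-degree orbit has several positions
(the 4-path's middle pair, every position of a cycle or clique), any one
of them may host the intermediate, and a node subset is counted once per
graphlet type regardless of how many valid assignments it admits.

Counting is by seed-anchored ESU-style enumeration: connected subsets
are grown so that each subset is visited exactly once (rooted at its
lowest-index node with exclusive-neighbourhood extension), pruning any
branch that already contains two non-seeds, since no supergraph of it
can satisfy the constraint. This makes the census linear in the number
of constrained occurrences rather than in the full graphlet census of
the interactome, which is what makes 100-fold permutation testing
affordable. The enumeration is checked against exhaustive
subset-enumeration oracles in the test suite.

### Permutation null and z-test

The null model preserves the degree sequence exactly: double-edge swaps
replace (a,b),(c,d) on four distinct nodes with (a,c),(b,d) — the
orientation of the second edge is randomized, so both rewirings are
reachable — rejecting any swap that would duplicate an existing edge.
Each permuted network uses ⌈swap_factor·|E|⌉ attempted swaps with
swap_factor = 10, a standard mixing allowance (the move itself, not the
count, is what the method prescribes). A swapped-in edge (a,c) inherits
the confidence of the displaced (a,b), so the confidence multiset of the
network is invariant and downstream flux distributions remain
comparable.

For each graphlet, z = (observed − mean)/sd over the permuted counts,
with the sample (ddof = 1) standard deviation over 100 permutations;
significance is one-sided, z > 1.65 (the 5% normal critical value 1.645
as conventionally quoted). When the null is degenerate (sd = 0) a
graphlet is significant only if its observed count strictly exceeds
every permuted count. The union of all matched nodes and induced match
edges of the significant graphlets is the graphlet-guided network (GGN),
with confidences inherited from R; G0 matches enter the union whenever
G0 is significant.

### Propagation and flux

Personalized PageRank iterates p ← (1−λ)·π + λ·W·p with W the
degree-normalized adjacency operator (uniform transition over
neighbours, independent of edge confidence) and π the normalized seed
weights. λ defaults to 0.85, the conventional damping; the restart
distribution is the personalized one because seed weights must shape
p — a `teleport_mode="uniform"` flag gives the textbook uniform-restart
variant for comparison. Iteration stops when the L1 change drops below
1e-8 (diagnostics carry `iterations_used` and a `converged` flag); mass
on degree-zero nodes is redistributed to π each step so Σp = 1 is
maintained to machine precision.

Each edge e = {u, t} receives directional fluxes f_{u→t} =
p(u)·c(e)/deg(u) and symmetrically for t→u, with deg taken in the
*reference* interactome — fluxes are a property of the full network, so
GGN trimming never changes an edge's score. The edge score is
f(e) = −log min(f_{u→t}, f_{t→u}); taking the minimum makes an edge only
as good as its weaker direction, and the degree denominator is the hub
penalty. The log base (10 by default, e available) only scales f(e) and
therefore shifts which edge first exhausts a τ budget in borderline
cases; it is recorded in the run metadata.

### Selection

GGN edges are ranked by descending min-flux (ascending f(e)) and taken
in order while the cumulative f(e) stays below τ·F, where F = Σ f(e)
over the finite-score GGN edges; the edge that first reaches the budget
is included, so τ = 1 keeps every finite-score edge and τ = 0 keeps
none. Ranking by descending raw flux rather than descending −log flux is
deliberate: the −log ordering would admit the *weakest* edges first,
contradicting the goal of keeping high-confidence, high-propagation
interactions (a `literal_descending_score` flag provides the reversed
ordering for comparison). Edges with zero min-flux (an endpoint
unreached by propagation) get an infinite score and never enter the
selection. τ defaults to 0.5; it is the main sensitivity dial and should
be tuned per application.

### Modules and enrichment

Louvain community detection (seeded, resolution 1.0 by default, topology
only) partitions the inferred network; each (module, term) pair is
tested with the exact hypergeometric upper tail P[X ≥ k] for X ~
HG(M, K, n) and Benjamini–Hochberg adjusted across all pairs at FDR
0.05. The default universe is the annotated interactome nodes —
unannotated nodes can never contribute to an overlap and would inflate
M — with an `interactome` mode (M = |V_R|) for cross-tool comparability.
Enrichment profiles over a shared vocabulary (binary by default:
term significant in ≥1 module; a −log10-adjusted-p weighted mode is
available) are compared by cosine similarity; an average-linkage
hierarchical clustering convenience is provided for stratifying contexts
but the linkage and cut are explicitly a package choice, not part of the
method.

## Evaluation utilities

Recovery against a gold standard is summarized by step-wise (trapezoid-
free) AUPRC — node ranking by p(v), edge ranking by min-flux, negatives
being all reference nodes/edges outside the truth, with the
positives-to-negatives ratio reported so different negative regimes can
be compared — plus point precision/recall/F1 at the selected network.
Hub trimming reports, for the ⌈0.2·|V|⌉ highest-degree reference nodes,
the reduction ratio RR(h) = 1 − deg_trimmed(h)/deg_ref(h). Scale-free
character is measured by least squares on (log₁₀ k, log₁₀ N(k)) over
non-empty degree bins, reporting γ = −slope and R²; at least three
distinct degrees are required. A seed-holdout cross-validation utility
masks one fold of seeds and scores recovery of the masked nodes.

## The synthetic benchmark

`generate_interactome` produces a Barabási–Albert preferential-
attachment graph (default attachment 2), whose heavy-tailed degree
distribution reproduces the hub structure the method must cope with;
confidences are uniform on (0, 1] or Beta(4, 2) (skewed high, as curated
interactomes are). `plant_pathway` grows a random connected induced
subgraph (default 25 nodes on a 500-node interactome), mixes its
internal edge confidences toward 1 with weight 0.5 — a recoverable but
not trivial signal — samples ⌈0.4·size⌉ seeds from it, and emits one
annotation term for the pathway plus five degree-matched decoy terms so
that enrichment cannot succeed through set size or hubness alone.

What the generator does *not* emulate: measurement noise on seed
weights, false-positive seeds outside any pathway, edge-confidence
miscalibration, multiple overlapping pathways, or patient-level
heterogeneity. Passing the recovery benchmark therefore shows that the
pipeline concentrates selection on a confidence- and topology-marked
subgraph around the seeds far better than chance — not that it resolves
overlapping pathways or survives noisy seed sets on real interactomes.

## Numerical and design notes

- Duplicate input edges keep the maximum confidence; self-loops are
  dropped; node identifiers are opaque case-sensitive strings; directed
  input is symmetrized.
- Seeds missing from the interactome are dropped (coverage is reported);
  an all-absent seed set is a fatal error; weightless seeds get 1.0, and
  an unweighted interactome gets confidence 1.0 on every edge.
- Selection tie-breaks are lexicographic on node ids after the flux key,
  so runs are bit-reproducible for a fixed rng seed; all randomness
  (swaps, generator, Louvain) flows from explicit seeds.
- F sums over GGN edges only: the selection budget measures the trimmed
  network's own score mass, not the reference's.
- Benchmark problem sizes used by the test and acceptance runs (500-node
  interactomes, 25-node pathways, 100 permutations, 20 replicate
  instances) were chosen as the smallest sizes at which the scale-free
  topology, the permutation null and the paired recovery comparison are
  all well-behaved; they are package defaults, and everything scales to
  larger interactomes through the same API.

## Known limitations

- The graphlet census is restricted to orders 2–4 (no order-5 graphlets,
  no orbit-degree vectors); very sparse seed sets can leave no graphlet
  significant, in which case the GGN and the inferred network are empty
  by design (with a warning) rather than falling back to propagation
  alone.
- The permutation z-test assumes approximate normality of permuted
  counts; with very small counts the sd-zero tie rule effectively turns
  it into an exceedance test.
- PageRank transitions ignore edge confidences (confidence enters
  through the flux, not the walk); an edge-weighted walk is a possible
  variant, not implemented.
- No identifier normalization: callers must harmonize gene/protein ids
  across interactome, seeds and annotation sets beforehand.
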