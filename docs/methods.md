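# Methods

## Data model

Input is a breakpoint table: one row per chromosomal aberration with a sample
name, a cancer-type label, a mutation type, and two breakpoints written as
`chrom:start..end`. Only chromosome identity is used downstream; base-pair
coordinates are parsed (1-based, as printed) and retained in the record for
forward compatibility. The chromosome universe is fixed at 24 nodes
(autosomes 1–22, X → 23, Y → 24); mitochondrial and unplaced contigs are
rejected at ingestion and counted in a skip report rather than raising.
Mutation types follow the seven-value vocabulary of COSMIC structural exports
(inverted orientation, noninverted orientation, inversion, deletion, tandem
duplication, insertion, unknown); every interchromosomal event is typed
`unknown`, so the six typed kinds occur only on self-loops. Duplicate rows
(identical sample and endpoints) are retained: the graphs are multigraphs and
repetition of an aberration is signal, not noise.

## Graph construction

All aberrations of one sample form one directed multigraph on the 24
chromosomes, edge direction running from the "Location From" chromosome to
the "Location To" chromosome, intrachromosomal events as self-loops. Three
edge modes support the ablation experiments: `inter` (self-loops dropped),
`intra` (only self-loops), `integrated` (everything).

Node features default to the adjacency-count row (d = 24): entry (u, w) is
the number of edges u → w, so node identity is carried implicitly by row
order and the matrix total equals the edge count. A richer scheme
(`adjacency_row_plus_types`, d = 31) appends the 7-dim count vector of each
chromosome's self-loop mutation types, since typed mutation kinds exist only
for intrachromosomal events. Edges carry their mutation type as an attribute,
but the network consumes node features only; the feature scheme is recorded
in every checkpoint.

## Average connectivity and filtering

kappa(u, v) is the maximum number of pairwise edge-disjoint u–v paths on the
symmetrized multigraph: each directed edge contributes one unit of undirected
capacity, parallel edges add capacity, self-loops contribute nothing (they
cannot lie on a u–v path). It is computed as unit-capacity maximum flow with
BFS augmenting paths (Edmonds–Karp), which Menger's theorem equates with the
edge-disjoint path count. We implement the edge-disjoint (flow) version and
expose an internally node-disjoint variant behind a flag for sensitivity
analysis. The average connectivity is

    kappa_bar(G) = sum_{u<v} kappa(u, v) / C(24, 2),

averaged over all 276 unordered pairs whether adjacent or not. The
symmetrization follows from the unordered-pair denominator; edge direction
matters only to the classifier. Pairs with an isolated endpoint are skipped
(their flow is zero by construction), which makes scoring sparse cohorts
cheap.

Filtering keeps a sample iff kappa_bar ≥ tau_low (default 0.3, boundary
inclusive), with an optional upper threshold tau_high (default off) for the
complementary reading that extremely dense graphs can also be uninformative.
kappa_bar is always computed on the integrated graph, then the chosen edge
mode restricts what the classifier sees: an intra-only graph always has
kappa_bar = 0, so filtering on the mode-restricted graph would empty the
intrachromosomal experiment entirely.

Correctness of the flow solver is established two independent ways in the
test suite: against an exhaustive trail-packing oracle
(`brute_force_disjoint_paths`, exponential, refuses graphs above 10 edges)
on 500 random small multigraphs, and against networkx maximum flow on
capacity graphs. The oracle enumerates every u–v trail and recursively packs
edge-disjoint sets; any set of edge-disjoint trails can be shortened to
paths within the same edge set, so the packing optimum equals the path
count.

## Classifier

Architecture: `n_hubs` stacked graph-attention layers (default 6, the
operating point of the classifier; configurable 1–10), global max pooling
over the 24 node embeddings, a dense layer, log-softmax. Each layer
transforms embeddings with a learned matrix W and aggregates node u's
in-neighborhood with attention coefficients softmax-normalized over the
incoming edges, scored by LeakyReLU(a_src·Wh_v + a_dst·Wh_u) — the standard
additive-attention construction, with the score decomposed into per-node
scalars so the forward pass stays node-sized. The aggregated message passes
through an ELU. After n layers each chromosome's embedding summarizes
aberrations up to n hops away.

Choices the architecture leaves open, and what this package does:

- **Self-loops for message passing** are added to every node so each
  chromosome retains its own state across layers; isolated chromosomes then
  have a well-defined (self-only) neighborhood and edgeless graphs remain
  valid inputs.
- **Parallel edges** enter the attention softmax as a multiset by default: a
  neighbor connected by k aberrations appears k times, so aberration
  multiplicity shifts attention mass. `dedup_neighbors=True` collapses them.
- **Hidden width 64, one attention head** are package defaults; multiple
  heads concatenate. Dropout (rate 0.2) applies to node features before each
  layer, only during training.
- **Loss** is the mean multiclass negative log likelihood of the true class
  under the log-softmax output.
- **No early stopping**: training runs exactly `max_epochs` (default 200)
  epochs of Adam (lr 0.001, batch size 10).

Class imbalance: per-class weights proportional to inverse frequency,
rescaled to mean 1, are used as per-graph sampling probabilities; each epoch
draws n_train graphs with replacement, so expected class frequency in batches
is uniform (verified by a chi-square test in the suite).

Determinism: parameter initialization (Glorot uniform), batch sampling and
dropout masks all derive from `config.seed` via two `numpy` generator
streams (seed for init, seed+1 for the training stream); two runs with one
seed produce bitwise-identical histories, checkpoints and reports.
Prediction ties break toward the lowest class index (first argmax).
Divergence (non-finite loss) aborts with a diagnostic rather than
continuing.

### Numerical core

The network runs on a small reverse-mode autodiff engine over numpy arrays
(`chromgat.nn.autodiff`): a tape of array ops — broadcasting arithmetic,
matmul, elementwise nonlinearities, reductions, reshape — plus four
graph-structured ops: constant-sparse matmul (gather/scatter as CSR
products), per-segment softmax (stabilized by subtracting the detached
per-segment maximum, which changes neither value nor gradient), an
attention-weighted aggregation that assembles the sparse coefficient matrix
per forward pass (parallel edges sum their coefficients), and a blocked
row-max for pooling whose gradient routes to the first argmax row per
coordinate. Every op's gradient is validated against central finite
differences in the test suite. Log-softmax rows are stabilized with a
detached row max. Adam follows the standard bias-corrected update
(β = 0.9/0.999, ε = 1e-8).

## Baselines

The comparison models see each aberration independently as a 55-dim one-hot
vector (source chromosome 24 + sink chromosome 24 + mutation type 7) and are
standard scikit-learn estimators: an MLP with three hidden layers of 60 ReLU
units, SVM with linear and polynomial kernels, and kNN with configurable k
and metric (Minkowski, Euclidean, or Mahalanobis with ridge-regularized
training covariance — the raw covariance of one-hot blocks is singular).
Splits are by sample, never by aberration, so no sample leaks rows across
the split. Evaluation defaults to per-aberration; a per-sample mode
(majority vote over a sample's rows) is available, since either unit is a
defensible reading and reports always state theirs.

## Synthetic cohorts

The generator emulates a COSMIC-style export. Per sample: an aberration
count from a truncated negative binomial (spanning sparse to dense graphs);
per aberration, intra vs inter by a fixed rate (default 0.75 — in real tumor
catalogues intrachromosomal events outnumber interchromosomal roughly three
to one); interchromosomal pairs from a class-specific signature distribution
mixed with uniform background; intrachromosomal events on a uniform
chromosome with a typed mutation kind. Interchromosomal events are always
typed `unknown`, so class identity lives entirely in the pair signature.

The `separable` preset (three classes with disjoint two-pair signatures,
intra rate 0.5, count mean 100 with dispersion 2, background rate 0.5) was
calibrated once so that a clear majority (roughly 70%) of samples passes the
default 0.3 connectivity filter while the rest genuinely falls below it; at
the default threshold the filter therefore partitions the cohort rather
than rubber-stamping it. A kappa_bar of 0.3 requires on the order of 14
chromosomes to be joined in one connected component, which anchors the count
distribution's scale.

What the generator does *not* emulate: genomic positions within chromosomes
(drawn uniformly, never interpreted), clonal structure, mutation-rate
realism, or class-dependent intrachromosomal patterns. Passing tests on
these cohorts therefore demonstrates that the pipeline recovers
interchromosomal co-occurrence structure when it exists; they say nothing
about how much such structure real tumor catalogues contain.

## Problem sizes and tolerances

The learning-sanity experiment uses the separable cohort at 200 samples per
class with full default training (200 epochs); the inter/intra ablation
retrains at 40 epochs, by which point the inter-mode model has long
converged and the intra-mode model has no signal to find at any epoch count;
end-to-end determinism checks use a 30-per-class cohort at 10 epochs, since
determinism is size-independent. Oracle-equivalence suites use 500 random
multigraphs with at most 5 nodes and 8 edges (the exhaustive oracle is
exponential). Attention normalization is asserted to 1e-6; finite-difference
gradient checks to a relative 1e-4.

## Known limitations

- Whole chromosomes are the only resolution: no within-chromosome binning,
  so two rearrangements joining the same chromosome pair at different loci
  are indistinguishable.
- The flow solver is pure Python; it is fast for 24-node multigraphs but not
  intended for larger node universes.
- A single train/test split (stratified, seeded) stands in for
  cross-validation.
- Baselines are deliberately simple comparators, not tuned competitors.
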