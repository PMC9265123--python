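# chromgat

Cancer-type classification from chromosomal rearrangement endpoints.

Structural chromosomal aberrations — translocations, deletions, inversions,
duplications — are catalogued in tumor databases as breakpoint pairs
("Location From", "Location To") per sample. `chromgat` asks whether the
*wiring pattern* of these rearrangements alone identifies the cancer type.
It is aimed at computational cancer-genomics researchers working with
COSMIC-style structural-variant exports.

## Method

Each tumor sample becomes a directed multigraph G(V, E) on the fixed node set
V = {1, …, 24} of human chromosomes (X = 23, Y = 24). Every aberration adds
one edge from its source to its sink chromosome; intrachromosomal events are
self-loops; repeated aberrations keep parallel edges. Each node carries its
adjacency-count row as a feature vector.

Graphs are scored by **average connectivity**

```
kappa_bar(G) = sum_{u<v} kappa_G(u, v) / C(24, 2)
```

where kappa_G(u, v) is the maximum number of pairwise edge-disjoint u–v paths
on the symmetrized multigraph, computed as unit-capacity maximum flow with
BFS augmenting paths (by Menger's theorem the two are equal). Samples with
kappa_bar below a threshold (default 0.3) carry too few interdependent
rearrangements to be informative and are filtered out.

The classifier is a **graph attention network**: n stacked message-passing
layers (default n = 6), in which node u aggregates its neighborhood ξ(u) as
m(u) = Σ_{v∈ξ(u)} α_{u,v} · W h_v with softmax-normalized learned attention
α, followed by global max pooling over the 24 node embeddings, a dense layer
and log-softmax over cancer types. Training minimizes the multiclass negative
log likelihood with Adam (lr 0.001, batch 10, ≤ 200 epochs, dropout 0.2);
class imbalance is handled by drawing batches with inverse-frequency class
weights. Flat-feature baselines (feed-forward network, linear/polynomial SVM,
kNN) on per-aberration one-hot encodings are included for comparison, along
with a synthetic cohort generator so the whole pipeline runs with no
external download.

The network itself (attention layers, pooling, loss, Adam, weighted
sampling) is implemented in this package on a small vectorized
reverse-mode autodiff core (`chromgat.nn.autodiff`) — see
`docs/methods.md` for the numerical details.

## Worked example

```python
from chromgat.breakpoints import group_by_sample, read_breakpoints
from chromgat.connectivity import connectivity_profile
from chromgat.filtering import FilterConfig, filter_graphs, split_dataset
from chromgat.graphs import build_cohort
from chromgat.metrics import report_from_labels
from chromgat.nn.model import GNNConfig, predict, train
from chromgat.synthetic import make_separable_cohort

make_separable_cohort(n_per_class=40, seed=0, path="cohort.tsv")
records = read_breakpoints("cohort.tsv").records
graphs = build_cohort(group_by_sample(records))
profiles = [connectivity_profile(g) for g in graphs]
kept, dropped = filter_graphs(graphs, profiles, FilterConfig(tau_low=0.3))
print(f"{len(graphs)} graphs, {len(kept)} kept at kappa_bar >= 0.3")

split = split_dataset(kept, test_fraction=0.2, seed=0)
state = train(split, GNNConfig(n_hubs=6, max_epochs=60, seed=0))
labels, probs = predict(state, split.test)
report = report_from_labels([g.label for g in split.test], labels, state.class_order)
print(f"test accuracy: {report.accuracy:.3f}")
for cls, m in report.per_class.items():
    print(f"{cls:<12} precision {m.precision:.2f}  recall {m.recall:.2f}  "
          f"f1 {m.f1:.2f}  support {m.support}")
```

Output:

```
120 graphs, 89 kept at kappa_bar >= 0.3
test accuracy: 1.000
breast       precision 1.00  recall 1.00  f1 1.00  support 6
pancreatic   precision 1.00  recall 1.00  f1 1.00  support 7
prostate     precision 1.00  recall 1.00  f1 1.00  support 5
```

The synthetic cohort gives each class a disjoint pair of signature
translocations (e.g. 1→2 and 3→4 for "breast") on top of shared background
noise, so 120 sample graphs are generated, the 89 with enough connected
structure survive the filter, and the attention network recovers the class
signatures perfectly on the held-out samples.

The same flow is available from the shell:

```
chromgat simulate --preset separable --n 40 --seed 0 --out cohort.tsv
chromgat pipeline --in cohort.tsv --out run/ --hubs 6 --seed 0
```

which writes the trained checkpoint, per-epoch training log, confusion
matrices (raw and column-normalized) and an evaluation report under `run/`.

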