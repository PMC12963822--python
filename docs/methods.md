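# Methods

## Problem and model

`gatmerip` scores every gene in a protein–protein interaction (PPI)
network for functional importance given two observed channels per gene
and dataset: RPM-normalized expression and aggregated m5C peak
enrichment from MeRIP-seq quantification. The premise is that
functionally important m5C targets are distinguished not only by their
own modification and expression levels but by their network context, so
the scorer is a graph neural network that propagates the two-channel
signal over the PPI graph.

A gene is a positive training example (y = 1) in a dataset when it
carries at least one retained m5C peak there; every other network gene
is a negative (y = 0). This makes the task self-supervised binary
classification of "modified vs. not" — no external importance labels
enter training, so held-out functional gene lists remain a legitimate
evaluation ground truth.

### Feature construction

1. Peaks of one dataset are aggregated per gene. The default
   aggregation is the **sum** of peak RPMs (a gene with two peaks at
   0.2 and 0.3 RPM gets 0.5); `max` is available as an alternative for
   users who prefer the strongest-peak reading. The sum was chosen
   because it preserves total enrichment mass for multi-peak genes.
2. Weakly supported positives are demoted: a positive must have
   expression ≥ 1.0 RPM and m5C ≥ 0.1 RPM (strictly-below values fail;
   the boundary survives). Failing genes are **demoted to negatives**
   (m5C reset to 0) rather than deleted, because the label definition
   requires every network gene to remain present as a y = 0 node.
3. Both channels are Z-scored within each dataset using the population
   (n-denominator) standard deviation. A constant channel maps to all
   zeros. Network genes missing from a dataset's table are imputed with
   the Z-value a 0-RPM gene would receive under that dataset's
   standardization.

An independent differential-peak filter (|log2 FC| ≥ log2 1.5 and
p < 0.05, both directions counted) is provided for peak tables carrying
differential statistics; it does not participate in model training.

### Graph

Interactions from any number of source databases are merged;
self-interactions are dropped at read time, duplicate pairs collapse to
one interaction whose categorical edge type follows a fixed source
precedence (default: order of first appearance; configurable). Each
undirected interaction is stored as two directed edges of weight 1 so
message passing can treat the two directions separately while
preserving the undirected biology. Node order is lexicographic over
symbols, making every downstream computation platform-reproducible.

### Architecture

Three cascaded graph-attention layers: 2 heads × (2 → 16) concatenated
to 32; 2 heads × (32 → 16) concatenated to 32; one head 32 → 1 logit,
sigmoid to a score in (0, 1). Batch normalization (eps 1e-5, momentum
0.1) follows layers 1 and 2, then ELU, then dropout 0.3. Each layer owns
a 32-dimensional embedding table over edge types. The attention logit of
head h for an edge j → i of type t is

    e_ij = LeakyReLU( a_dst·W h_i + a_src·W h_j + P·g(t) ),   slope 0.2

normalized by softmax over the in-neighborhood of i. Published accounts
of this family of models rarely write the edge-conditioned term
explicitly; the form above (a learned projection P of the per-layer
type embedding g added inside the LeakyReLU) is this package's design,
chosen so the edge information enters exactly where neighbor features
do. A structural self-loop with a reserved edge type is added to every
node so isolated genes have a defined neighborhood. Dropout masks node
representations after each normalized layer; masking attention
coefficients as well is off by default (`attention_dropout`).

Initialization: Glorot-uniform for feature transforms and attention
vectors, zeros for biases and edge projections, uniform(−0.1, 0.1) for
embedding tables. Zero edge projections mean edge types are invisible
at initialization and fade in through learning, and they make attention
over feature-identical neighborhoods exactly uniform at the start.

The whole model, its backpropagation and Adam are implemented on NumPy
via a small reverse-mode autodiff engine (`_autodiff.py`) with exactly
the operator set the model needs. Scatter-style accumulations order
their summands canonically by (segment, value), so forward passes are
*bitwise* equivariant under node relabeling — a property the test suite
asserts with exact equality. Gradient correctness is checked against
central finite differences (relative error < 1e-4).

### Training

All datasets share the topology and the parameters. (gene, dataset)
pairs are split 80/20 into train/validation, stratified by
dataset × label; each stratum contributes round(0.2 × size) validation
samples with exact .5 ties resolved downward, and a stratum too small
to contribute goes entirely to training with a warning. Each epoch runs
one full-graph forward/backward per dataset (Adam, lr 5e-4, weight
decay 1e-4 in the coupled L2 form), with the BCE masked to the
transductive train split; validation loss is the eval-mode BCE masked
to the validation split, averaged over datasets. Training stops at 200
epochs or after 30 epochs without validation improvement, returning the
parameters of the best epoch (first epoch on exact ties). There is no
learning-rate schedule. Final raw gene scores are eval-mode sigmoid
outputs averaged across datasets, reported alongside Min-Max and
Z-score normalizations and 1-based ranks (descending score, gene-symbol
tie-break). Constant score vectors map to Min-Max 0.5 and Z 0.

## RWR baseline

Random walk with restart on the undirected graph's column-normalized
adjacency: p ← (1−r) Wᵀp + r p₀, p₀ uniform over seed genes, restart
probability r defaulting to 0.7 (a common network-propagation setting;
exposed in config since no canonical value exists for this use).
Iteration stops when the L1 change drops below 1e-8. Degree-0 genes are
dangling; their outgoing mass teleports to the restart distribution, so
p remains a probability distribution at every iteration. A closed-form
linear solve (I − (1−r)M)⁻¹ r p₀, with dangling columns of M replaced
by p₀, serves as the testing oracle — the two routes agree to 1e-6 L∞
on every tested graph. Seed genes are sampled uniformly without
replacement from modified (label-1) genes; seed mass is unweighted by
m5C level.

## Robustness benchmark

Degree-preserving randomization rewires by repeated double-edge swaps
((a–b, c–d) → (a–d, c–b); proposals creating self-edges or duplicates
are rejected and retried), defaulting to 10× the undirected edge count
per network, preserving the node set, edge count and exact degree
sequence. Edge types travel with their first endpoint, which keeps the
type multiset intact even though type–pair assignments randomize.

The protocol samples 100 modified seed genes, builds two independent
ensembles of 100 randomized networks, takes each network's top-200
candidates per method and forms each ensemble's consensus as the genes
present in at least 50% of its candidate sets (the published protocol
does not state how per-network results combine; majority consensus is
this package's choice, isolated behind one function). The attention
method's fast filter ranks non-seed genes by deg(g) × (mean seed
degree) with a lexicographic tie-break — a reconstruction constrained
by the published description that it uses only the degree information
of candidate and seed genes, which forces invariance under
degree-preserving rewiring and hence a symmetric difference of exactly
0 between ensembles. RWR's candidate sets depend on actual wiring and
generally differ. A timing harness reports median/IQR wall times;
orderings are asserted in tests, ratios never, because fold-speedups
are hardware-bound.

AUROC is the Mann–Whitney statistic of the scores against a functional
gene list (ties half-weighted); over-representation of top-k genes in
named gene sets uses the hypergeometric upper tail with
Benjamini–Hochberg adjustment.

## Synthetic data

The generator emulates the statistical shape of the real inputs, not
their content: a Barabási–Albert graph (2000 genes, 3 edges per new
node) for the heavy-tailed PPI degree distribution; 6 datasets; 30% of
genes modified per dataset; 5% planted functional genes. Functional
genes are drawn hub-biased (weight (1−b) + b·deg/max deg, b = 0.5) and
clustered (each next pick comes from the chosen set's neighborhood with
probability b), are modified more often (label weight 1 + 2×effect
size), and have log-normal channels shifted by effect size 2.0 in
log-m5C and half that in log-expression (noise sd 1.0, background
median expression 5 RPM). Modified genes' values are floored at the
1.0/0.1 RPM filter cuts so planted positives always survive filtering.
Setting effect size and hub bias to 0 removes every functional signal —
labels, features and placement become exchangeable — which is the null
construction used to check that downstream AUROC sits at chance.

What the fixtures do **not** model: correlated expression between
interacting genes, dataset-specific batch structure, peak-level
resolution (the generator emits gene-level values directly), and any
real PPI network's size or clustering coefficients. Passing tests
therefore demonstrate algorithmic correctness and recoverability of a
planted signal, not biological performance.

## Problem sizes and numerical choices

The test suite trains the full model at the generator's default design
(2000 genes, 6 datasets, ≤ 200 epochs) for the recovery check, and uses
a 500-gene, 2-dataset, ≤ 60-epoch instance per replicate for the
10-replicate null check — the null needs replication more than size,
and at 500 genes the chance-level AUROC estimate is already tight.
The acceptance script runs the full 2 × 100-network protocol at 2000
genes. Convergence/equality tolerances: attention normalization 1e-6,
RWR iteration 1e-8 (oracle agreement 1e-6), Z-scoring 1e-9, gradient
check 1e-4 relative at eps 1e-6. Score TSVs carry 6 decimals.

## Known limitations

* Full-graph training only; no mini-batching, so very large PPI
  networks are memory-bound.
* The degree-filter reconstruction is one of several formulas
  compatible with the published degree-only description; any
  strictly-monotone function of degree yields the same candidate sets,
  so the choice is immaterial to the reported invariance.
* Gene identifier harmonization across source databases is assumed done
  upstream; symbols are only upper-cased and whitespace-stripped.
* The RWR restart probability of the original comparison is unknown;
  conclusions about RWR here are conditional on r = 0.7.
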