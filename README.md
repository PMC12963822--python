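# gatmerip

Prioritization of functional m5C-modified genes on protein–protein
interaction networks with a graph attention network, plus the
random-walk-with-restart (RWR) baseline it is benchmarked against.

## What problem this solves

MeRIP-seq experiments for RNA 5-methylcytosine (m5C) yield, per dataset,
two numbers for each gene: an RPM-normalized expression level and an
aggregated m5C peak enrichment. Which of the thousands of modified genes
actually matter functionally? This package answers by exploiting network
context: genes are nodes of a merged PPI graph (e.g. BioGRID + HuRI +
PICKLE edge lists), and a three-layer graph attention network (GAT)
learns, self-supervised, to classify "carries an m5C peak" (y = 1)
versus "does not" (y = 0) from the two standardized channels
x = (z_expr, z_m5C) propagated over the graph. Its sigmoid output is the
per-gene importance score; no external importance labels enter training,
so curated driver/disease gene lists remain usable as evaluation ground
truth. It is aimed at computational epitranscriptomics groups who
already run peak callers (e.g. exomePeak2) and want a principled,
reproducible ranking step downstream.

The attention of head *h* for an edge *j → i* of categorical type *t*
(type = source database by default) is

    e_ij = LeakyReLU( a_d·W h_i + a_s·W h_j + P·g(t) ),
    α_ij = softmax_{j ∈ N(i) ∪ {i}} (e_ij)

with per-layer edge-type embedding g and projection P. Dimensions:
2 →(2 heads × 16)→ 32 →(2 heads × 16)→ 32 →(1 head)→ 1, batch-norm +
ELU + dropout 0.3 after layers 1–2, Adam (lr 5e-4, weight decay 1e-4),
BCE loss, 80/20 stratified transductive split, early stopping after 30
stale epochs, ≤ 200 epochs. The RWR comparator iterates
p ← (1−r)Wᵀp + r·p₀ from modified seed genes (r = 0.7 default). A
robustness benchmark compares both methods across two ensembles of 100
degree-preserving random networks; the GAT-side candidate filter uses
only degree information, making its candidate sets provably identical
across ensembles (symmetric difference 0), while RWR's drift.

See `docs/methods.md` for the full model description, design choices
and limitations.

## Worked example

Everything below is runnable offline; `simulate` writes a synthetic
scale-free network and feature tables with 5% planted functional genes.

```bash
cat > spec.yaml <<EOF
n_genes: 300
n_datasets: 2
seed: 5
EOF
gatmerip simulate --spec spec.yaml --outdir data
# wrote network (300 genes, 891 interactions), 2 feature tables and 15 truth genes to data

gatmerip train --network data/network.tsv \
    --features data/features_SYN1.tsv --features data/features_SYN2.tsv \
    --out model.json --log losses.tsv
# stopped after epoch 200; best validation loss 0.590328 at epoch 189; checkpoint -> model.json

gatmerip score --checkpoint model.json --network data/network.tsv \
    --features data/features_SYN1.tsv --features data/features_SYN2.tsv \
    --out scores.tsv
head -4 scores.tsv
# #gene_id  raw_score  minmax_score  z_score   rank
# G00182    0.475726   1.000000      3.060828  1
# G00259    0.470923   0.983920      2.969305  2
# G00073    0.466578   0.969373      2.886504  3
```

`raw_score` is the dataset-averaged sigmoid output (probability-scale
importance), `minmax_score`/`z_score` its normalizations for
cross-method comparison, `rank` 1-based. Benchmarking against the
planted truth and the randomization protocol:

```bash
gatmerip benchmark --network data/network.tsv \
    --features data/features_SYN1.tsv --features data/features_SYN2.tsv \
    --truth data/truth.txt --checkpoint model.json \
    --robustness --n-networks 10 --n-seeds 20 --k 30 --out bench.json
# "auroc": 0.7265497076023392,
# "robustness": {
#   "degree_filter": {"consensus_a": 30, "consensus_b": 30, "n_differing": 0},
#   "rwr":           {"consensus_a": 16, "consensus_b": 11, "n_differing": 13}}
```

AUROC 0.73 against the planted functional genes on this deliberately
small demo (the default 2000-gene, 6-dataset design reaches ≈ 0.98 in
the test suite); the degree-information filter returns identical
candidate sets on both random-network ensembles (0 differing genes)
while RWR's consensus sets differ. Real data enters the same way:
`read_edge_list` for PPI TSV/BioGRID exports, `read_quantification` for
BED-style peak tables + expression TSVs, `read_gene_list` for
COSMIC/IntOGen/DisGeNET-style truth files.

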