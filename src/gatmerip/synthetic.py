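"""Synthetic PPI-like graphs and multi-dataset m5C features.

Emulates the statistical structure the model assumes: a scale-free
interaction graph (preferential attachment), per-dataset (expression,
m5C) channels on a shared gene universe, peak-presence labels, and a
planted set of "functional" genes that are hub-biased, mutually
adjacent, more often modified, and shifted upward in both channels.
Every quantity flows from one seeded generator, so a fixed seed gives
byte-identical output. These fixtures capture none of the biological
correlations of real MeRIP-seq data — they exist so the pipeline is
trainable and testable at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .benchmark import GroundTruth
from .data_io import EdgeListRecord
from .features import GeneFeature, zscore_by_dataset
from .ppi_graph import PPINetwork, build_network


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator design. Defaults are the package's standard study
    conditions; ``effect_size=0, hub_bias=0`` is the null construction
    under which planted genes are statistically indistinguishable."""

    n_genes: int = 2000
    attachment_edges_per_node: int = 3
    n_datasets: int = 6
    frac_modified: float = 0.3
    frac_functional: float = 0.05
    effect_size: float = 2.0
    noise_sd: float = 1.0
    hub_bias: float = 0.5
    seed: int = 0

    def __post_init__(self):
        problems = []
        if self.n_genes < 10:
            problems.append("n_genes must be >= 10")
        for name in ("frac_modified", "frac_functional"):
            if not 0.0 < getattr(self, name) < 1.0:
                problems.append(f"{name} must be in (0, 1)")
        if self.effect_size < 0:
            problems.append("effect_size must be >= 0")
        if not 0.0 <= self.hub_bias <= 1.0:
            problems.append("hub_bias must be in [0, 1]")
        if self.noise_sd <= 0:
            problems.append("noise_sd must be > 0")
        if self.attachment_edges_per_node < 1:
            problems.append("attachment_edges_per_node must be >= 1")
        if problems:
            raise ValueError("invalid SyntheticSpec: " + "; ".join(problems))


def _gene_name(i: int) -> str:
    return f"G{i:05d}"


def _plant_functional(G: nx.Graph, spec: SyntheticSpec,
                      rng: np.random.Generator) -> list[int]:
    """Choose planted genes: hub-biased and preferentially adjacent.

    With ``hub_bias=0`` the choice is uniform and non-clustered, which
    the null construction requires. Otherwise each next gene comes from
    the neighborhood of the already-chosen set with probability
    ``hub_bias`` (module structure), else from a degree-tilted draw.
    """
    n_func = max(1, round(spec.frac_functional * spec.n_genes))
    deg = np.array([G.degree[i] for i in range(spec.n_genes)], dtype=float)
    weights = (1 - spec.hub_bias) + spec.hub_bias * deg / deg.max()
    chosen: list[int] = []
    chosen_set: set[int] = set()
    while len(chosen) < n_func:
        frontier = sorted(
            {nb for c in chosen for nb in G.neighbors(c)} - chosen_set
        )
        if chosen and frontier and rng.random() < spec.hub_bias:
            pick = int(frontier[rng.integers(len(frontier))])
        else:
            w = weights.copy()
            w[list(chosen_set)] = 0.0
            pick = int(rng.choice(spec.n_genes, p=w / w.sum()))
        chosen.append(pick)
        chosen_set.add(pick)
    return chosen


def generate(spec: SyntheticSpec) -> tuple[PPINetwork, list[GeneFeature], GroundTruth]:
    """Produce (network, standardized features for all datasets, truth).

    Per dataset, ``frac_modified`` of the genes carry a peak (label 1),
    drawn with weight ``1 + 2*effect_size`` for planted genes. Modified
    genes get log-normal m5C levels (log-mean shifted by ``effect_size``
    for planted genes, floored at 0.1 RPM) and log-normal expression
    (half-size shift, floored at 1.0 RPM), so the low-signal filter
    keeps every planted positive; unmodified genes have m5C 0.
    """
    rng = np.random.default_rng(spec.seed)
    G = nx.barabasi_albert_graph(
        spec.n_genes, spec.attachment_edges_per_node, seed=int(rng.integers(2**31))
    )
    records = [
        EdgeListRecord(_gene_name(u), _gene_name(v), "synthetic")
        for u, v in sorted((min(e), max(e)) for e in G.edges())
    ]
    net = build_network(records)

    functional_idx = _plant_functional(G, spec, rng)
    functional = frozenset(_gene_name(i) for i in functional_idx)
    is_func = np.zeros(spec.n_genes, dtype=bool)
    is_func[functional_idx] = True

    n_pos = max(1, round(spec.frac_modified * spec.n_genes))
    label_w = np.where(is_func, 1.0 + 2.0 * spec.effect_size, 1.0)
    mu_expr = np.log(5.0)  # median 5 RPM background expression

    features: list[GeneFeature] = []
    for d in range(spec.n_datasets):
        ds = f"SYN{d + 1}"
        pos = rng.choice(spec.n_genes, size=n_pos, replace=False,
                         p=label_w / label_w.sum())
        label = np.zeros(spec.n_genes, dtype=int)
        label[pos] = 1
        shift = spec.effect_size * is_func
        expr = rng.lognormal(mu_expr + 0.5 * shift, spec.noise_sd, spec.n_genes)
        m5c = rng.lognormal(shift, spec.noise_sd, spec.n_genes)
        # floors keep every modified gene above the low-signal cuts
        expr = np.where(label == 1, np.maximum(expr, 1.0), expr)
        m5c = np.where(label == 1, np.maximum(m5c, 0.1), 0.0)
        for i in range(spec.n_genes):
            features.append(
                GeneFeature(
                    gene_id=_gene_name(i),
                    dataset_id=ds,
                    expression_rpm=float(expr[i]),
                    m5c_rpm=float(m5c[i]),
                    label=int(label[i]),
                )
            )
    return net, zscore_by_dataset(features), GroundTruth(functional)


def make_toy_quantification(
    n_peaks: int, outdir: str | Path, seed: int = 0
) -> tuple[Path, Path]:
    """Write a small peak table + expression table exercising every
    filter branch; returns (peaks_path, expression_path).

    Besides ``n_peaks`` random peaks, the table always contains: a gene
    with exactly two peaks (aggregation), a gene at expression 0.99 RPM
    and one at m5C 0.09 RPM (both low-signal rejections), boundary rows
    at exactly 1.0 / 0.1 RPM, and peaks just below and above the
    1.5-fold differential cut.
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    rng = np.random.default_rng(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    peaks_path = outdir / "toy_peaks.tsv"
    expr_path = outdir / "toy_expression.tsv"

    rows: list[tuple] = []           # chrom start end gene m5c strand lfc p
    expression: dict[str, float] = {}

    def add(gene, m5c, lfc, p, expr):
        start = int(rng.integers(1_000, 1_000_000))
        rows.append(("chr1", start, start + 200, gene, m5c,
                     "+" if rng.random() < 0.5 else "-", lfc, p))
        expression[gene] = expr

    # fixed branch-exercising genes
    add("TOYDUP", 0.20, 1.0, 0.01, 5.0)     # two peaks -> aggregation
    add("TOYDUP", 0.30, -1.0, 0.01, 5.0)
    add("TOYLOWEXPR", 5.0, 1.0, 0.01, 0.99)  # fails expression >= 1.0
    add("TOYLOWM5C", 0.09, 1.0, 0.01, 5.0)   # fails m5C >= 0.1
    add("TOYBOUND", 0.10, 1.0, 0.01, 1.0)    # exact boundary: retained
    add("TOYFCLOW", 1.0, 0.55, 0.01, 5.0)    # |lfc| just under log2(1.5)=0.585
    add("TOYFCHI", 1.0, 0.60, 0.01, 5.0)     # just over the cut
    add("TOYPHI", 1.0, 1.0, 0.06, 5.0)       # p-value too large

    for i in range(n_peaks):
        gene = f"TOY{i:04d}"
        add(gene,
            float(np.round(rng.lognormal(0.0, 1.0), 4)),
            float(np.round(rng.normal(0.0, 1.0), 4)),
            float(np.round(rng.uniform(0.0, 1.0), 4)),
            float(np.round(rng.lognormal(np.log(5.0), 1.0), 4)))

    with open(peaks_path, "w") as fh:
        fh.write("#chrom\tstart\tend\tgene_id\tm5c_rpm\tstrand\tlog2_fc\tp_value\n")
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")
    with open(expr_path, "w") as fh:
        fh.write("#gene_id\texpression_rpm\n")
        for gene in sorted(expression):
            fh.write(f"{gene}\t{expression[gene]}\n")
    return peaks_path, expr_path
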