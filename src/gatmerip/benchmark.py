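"""Evaluation harness: AUROC, robustness across random networks, ORA, timing.

The robustness protocol mirrors the published comparison: sample modified
genes as seeds, build two independent ensembles of degree-preserving
random networks, derive a top-k candidate set on every network — for the
attention method via a filter that consumes only degree information, for
RWR by propagating from the same seeds — and compare each ensemble's
consensus set. Because the degree filter sees nothing but degrees, which
rewiring preserves, its symmetric difference is 0 by construction; RWR's
is generally not.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ppi_graph import PPINetwork, degree_preserving_randomize
from .rwr import RWRConfig, rwr, sample_seed_genes


@dataclass(frozen=True)
class GroundTruth:
    """Known functional genes (e.g. merged driver/disease gene lists)."""

    functional_genes: frozenset[str]

    def __post_init__(self):
        if not self.functional_genes:
            raise ValueError("ground-truth gene set is empty")


@dataclass
class RobustnessResult:
    """Consensus candidate sets from two random-network ensembles."""

    candidate_set_a: frozenset[str]
    candidate_set_b: frozenset[str]
    per_network_a: list[frozenset[str]] = field(default_factory=list)
    per_network_b: list[frozenset[str]] = field(default_factory=list)

    @property
    def n_differing(self) -> int:
        return len(self.candidate_set_a ^ self.candidate_set_b)


# ---------------------------------------------------------------------------
# AUROC
# ---------------------------------------------------------------------------

def auroc(scores, truth: GroundTruth) -> float:
    """Rank-based AUROC of the scores against the functional gene set.

    Equals the Mann-Whitney U statistic normalized by n+ * n-; ties count
    one half. ``scores`` may be a ScoreTable or a gene -> score mapping;
    the scored universe defines the evaluation set, and both at least one
    positive and one negative must be present in it.
    """
    mapping = scores.raw_scores() if hasattr(scores, "raw_scores") else dict(scores)
    if not mapping:
        raise ValueError("no scores to evaluate")
    genes = sorted(mapping)
    values = np.array([mapping[g] for g in genes], dtype=float)
    labels = np.array([g in truth.functional_genes for g in genes], dtype=bool)
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"degenerate ground truth: {n_pos} positives, {n_neg} negatives "
            "in the scored universe"
        )
    ranks = stats.rankdata(values)  # average ranks on ties
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# Degree-information candidate filter
# ---------------------------------------------------------------------------

def degree_based_candidate_filter(
    net: PPINetwork, seeds: frozenset[str] | set[str], k: int
) -> frozenset[str]:
    """Top-k non-seed genes scored from degree information alone.

    The score of gene g is deg(g) * (mean seed degree); since it depends
    only on the gene's degree and the multiset of seed degrees, the
    output is invariant under any degree-preserving transformation of
    the network. Ties break lexicographically on the gene symbol.
    """
    if not seeds:
        raise ValueError("seed set is empty")
    missing = [s for s in seeds if s not in net.node_index]
    if missing:
        raise KeyError(f"seed genes not in network: {sorted(missing)[:5]}")
    seed_deg = np.array([net.degrees[net.node_index[s]] for s in seeds], dtype=float)
    mean_seed_deg = seed_deg.mean()
    non_seed = [g for g in net.nodes if g not in seeds]
    if k > len(non_seed):
        raise ValueError(f"k={k} exceeds the {len(non_seed)} non-seed genes")
    scored = sorted(
        non_seed,
        key=lambda g: (-net.degrees[net.node_index[g]] * mean_seed_deg, g),
    )
    return frozenset(scored[:k])


# ---------------------------------------------------------------------------
# Robustness protocol
# ---------------------------------------------------------------------------

def _rwr_candidates(net: PPINetwork, seeds, k: int, rwr_config: RWRConfig
                    ) -> frozenset[str]:
    cfg = RWRConfig(
        restart_prob=rwr_config.restart_prob,
        tolerance=rwr_config.tolerance,
        max_iter=rwr_config.max_iter,
        seed_genes=frozenset(seeds),
    )
    p = rwr(net, cfg)
    order = sorted(
        (g for g in net.nodes if g not in seeds),
        key=lambda g: (-p[net.node_index[g]], g),
    )
    return frozenset(order[:k])


def robustness_protocol(
    net: PPINetwork,
    features,
    n_seeds: int = 100,
    n_networks: int = 100,
    k: int = 200,
    seed: int = 0,
    methods: tuple[str, ...] = ("degree_filter", "rwr"),
    rwr_config: RWRConfig | None = None,
    n_swaps: int | None = None,
) -> dict[str, RobustnessResult]:
    """Candidate-set stability across two random-network ensembles.

    Samples ``n_seeds`` modified genes from the feature table, builds two
    independent ensembles of ``n_networks`` degree-preserving
    randomizations each, collects every network's top-``k`` candidates
    per method, forms each ensemble's consensus (genes in >= 50% of its
    candidate sets) and reports the symmetric difference.
    """
    if not set(methods) <= {"degree_filter", "rwr"}:
        raise ValueError(f"unknown methods in {methods}")
    seeds_genes = sample_seed_genes(features, n_seeds, seed)
    base_rwr = rwr_config or RWRConfig()
    ss = np.random.SeedSequence(seed)
    ens_seeds = ss.spawn(2)

    results: dict[str, RobustnessResult] = {
        m: RobustnessResult(frozenset(), frozenset()) for m in methods
    }
    per_method: dict[str, tuple[list, list]] = {m: ([], []) for m in methods}
    for side, ens_ss in enumerate(ens_seeds):
        for child in ens_ss.spawn(n_networks):
            rnd = degree_preserving_randomize(
                net, n_swaps=n_swaps, seed=np.random.default_rng(child)
            )
            for m in methods:
                if m == "degree_filter":
                    cand = degree_based_candidate_filter(rnd, seeds_genes, k)
                else:
                    cand = _rwr_candidates(rnd, seeds_genes, k, base_rwr)
                per_method[m][side].append(cand)

    for m in methods:
        sets_a, sets_b = per_method[m]
        results[m] = RobustnessResult(
            candidate_set_a=_consensus(sets_a),
            candidate_set_b=_consensus(sets_b),
            per_network_a=sets_a,
            per_network_b=sets_b,
        )
    return results


def _consensus(candidate_sets: list[frozenset[str]]) -> frozenset[str]:
    """Genes present in at least half of the candidate sets."""
    counts: dict[str, int] = {}
    for s in candidate_sets:
        for g in s:
            counts[g] = counts.get(g, 0) + 1
    threshold = 0.5 * len(candidate_sets)
    return frozenset(g for g, c in counts.items() if c >= threshold)


# ---------------------------------------------------------------------------
# Over-representation analysis
# ---------------------------------------------------------------------------

def over_representation(
    top_genes: set[str] | frozenset[str],
    gene_sets: dict[str, set[str]],
    universe: set[str] | frozenset[str],
) -> pd.DataFrame:
    """Hypergeometric enrichment of ``top_genes`` in each named gene set.

    One-sided upper-tail p-values with Benjamini-Hochberg q-values,
    ordered by p. Gene sets are intersected with the universe first.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty universe")
    top = frozenset(top_genes)
    if not top <= universe:
        raise ValueError("top_genes must be a subset of the universe")
    rows = []
    for name in sorted(gene_sets):
        members = frozenset(gene_sets[name]) & universe
        overlap = len(top & members)
        # P(X >= overlap), X ~ Hypergeom(|U|, |set|, |top|)
        p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(members),
                                     len(top)))
        rows.append((name, len(members), overlap, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["gene_set", "n_set", "n_overlap", "p_value"])
    df["q_value"] = stats.false_discovery_control(df["p_value"], method="bh")
    return df.sort_values(["p_value", "gene_set"], ignore_index=True)


def read_gmt(path) -> dict[str, set[str]]:
    """GMT gene-set collection: name <tab> description <tab> genes..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT rows need >= 3 columns")
            sets[parts[0]] = {g.strip().upper() for g in parts[2:] if g.strip()}
    return sets


# ---------------------------------------------------------------------------
# Timing
# ---------------------------------------------------------------------------

def timing_harness(method, net: PPINetwork, repetitions: int = 3,
                   label: str | None = None) -> dict:
    """Median and IQR of wall time for ``method(net)`` — reported, never
    asserted: wall-clock ratios are hardware-dependent."""
    times = []
    for _ in range(repetitions):
        t0 = time.perf_counter()
        method(net)
        times.append(time.perf_counter() - t0)
    q1, med, q3 = np.percentile(times, [25, 50, 75])
    return {
        "label": label or getattr(method, "__name__", "method"),
        "n_nodes": net.n_nodes,
        "n_edges": net.n_undirected_edges,
        "repetitions": repetitions,
        "times": times,
        "median_s": float(med),
        "iqr_s": float(q3 - q1),
    }
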