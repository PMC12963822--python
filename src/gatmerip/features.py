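"""Per-gene, per-dataset feature engineering.

Turns peak and expression records into the two-channel input the model
consumes: gene expression (RPM) and aggregated m5C enrichment (RPM),
each Z-scored within its dataset. A gene is a positive (label 1) when it
carries at least one retained m5C peak in that dataset; all other genes
in the interaction network are negatives (label 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from collections import defaultdict

import numpy as np

from .data_io import ExpressionRecord, PeakRecord

FC_THRESHOLD_DEFAULT = 1.5
P_THRESHOLD_DEFAULT = 0.05
MIN_EXPRESSION_RPM = 1.0
MIN_M5C_RPM = 0.1


@dataclass(frozen=True)
class GeneFeature:
    """One gene's feature vector in one dataset."""

    gene_id: str
    dataset_id: str
    expression_rpm: float
    m5c_rpm: float
    expression_z: float = 0.0
    m5c_z: float = 0.0
    label: int = 0

    def __post_init__(self):
        if self.expression_rpm < 0 or self.m5c_rpm < 0:
            raise ValueError(f"{self.gene_id}: RPM fields must be >= 0")
        if self.label not in (0, 1):
            raise ValueError(f"{self.gene_id}: label must be 0 or 1")


def aggregate_peaks(peaks: list[PeakRecord], how: str = "sum") -> dict[str, float]:
    """Collapse multiple peaks per gene into one m5C level.

    Default is the sum of peak RPMs; ``how="max"`` keeps the strongest
    peak instead. All records must come from a single dataset.
    """
    if how not in {"sum", "max"}:
        raise ValueError(f"unknown aggregation {how!r}")
    datasets = {p.dataset_id for p in peaks}
    if len(datasets) > 1:
        raise ValueError(f"peaks span multiple datasets: {sorted(datasets)}")
    out: dict[str, float] = {}
    for p in peaks:
        if p.gene_id not in out:
            out[p.gene_id] = p.m5c_rpm
        elif how == "sum":
            out[p.gene_id] += p.m5c_rpm
        else:
            out[p.gene_id] = max(out[p.gene_id], p.m5c_rpm)
    return out


def build_features(
    peaks: list[PeakRecord],
    expression: list[ExpressionRecord],
    dataset_id: str,
    aggregation: str = "sum",
) -> list[GeneFeature]:
    """Assemble raw (unstandardized) features for one dataset.

    Peak-bearing genes get label 1 and the aggregated m5C RPM; genes seen
    only in the expression table get label 0 and m5C 0. Genes with peaks
    but absent from the expression table default to 0 RPM expression
    (they will then fail the low-expression filter).
    """
    m5c = aggregate_peaks([p for p in peaks if p.dataset_id == dataset_id],
                          how=aggregation)
    expr = {e.gene_id: e.expression_rpm for e in expression
            if e.dataset_id == dataset_id}
    feats = []
    for gene in sorted(set(m5c) | set(expr)):
        level = m5c.get(gene, 0.0)
        feats.append(
            GeneFeature(
                gene_id=gene,
                dataset_id=dataset_id,
                expression_rpm=expr.get(gene, 0.0),
                m5c_rpm=level,
                label=int(level > 0),
            )
        )
    return feats


def filter_low_signal(
    features: list[GeneFeature],
    min_expression: float = MIN_EXPRESSION_RPM,
    min_m5c: float = MIN_M5C_RPM,
) -> list[GeneFeature]:
    """Demote weakly supported positives.

    A positive survives only with expression >= 1.0 RPM and m5C >= 0.1 RPM
    (strictly-below values are filtered, so the boundary is kept). A gene
    failing either cut stays in the table as a label-0 node with its m5C
    level reset to 0 — the label definition needs every network gene
    present as a negative, so nothing is deleted. Negatives pass through
    untouched. Never creates a positive.
    """
    out = []
    for f in features:
        if f.label == 1 and (f.expression_rpm < min_expression
                             or f.m5c_rpm < min_m5c):
            out.append(replace(f, label=0, m5c_rpm=0.0))
        else:
            out.append(f)
    return out


def zscore_by_dataset(features: list[GeneFeature]) -> list[GeneFeature]:
    """Z-score both channels within each dataset (population sd).

    A constant channel maps to all zeros. Datasets with a single gene are
    rejected: a one-point standard deviation is meaningless.
    """
    by_ds: dict[str, list[GeneFeature]] = defaultdict(list)
    for f in features:
        by_ds[f.dataset_id].append(f)
    out = []
    for ds, group in by_ds.items():
        if len(group) < 2:
            raise ValueError(f"dataset {ds!r} has fewer than 2 genes")
        stats = dataset_standardization_stats(group)
        for f in group:
            out.append(
                replace(
                    f,
                    expression_z=_z(f.expression_rpm, stats["expression"]),
                    m5c_z=_z(f.m5c_rpm, stats["m5c"]),
                )
            )
    return out


def dataset_standardization_stats(
    features: list[GeneFeature],
) -> dict[str, tuple[float, float]]:
    """Per-channel (mean, population sd) over one dataset's raw RPMs."""
    datasets = {f.dataset_id for f in features}
    if len(datasets) != 1:
        raise ValueError(f"expected one dataset, got {sorted(datasets)}")
    expr = np.array([f.expression_rpm for f in features], dtype=float)
    m5c = np.array([f.m5c_rpm for f in features], dtype=float)
    return {
        "expression": (float(expr.mean()), float(expr.std())),
        "m5c": (float(m5c.mean()), float(m5c.std())),
    }


def _z(value: float, stats: tuple[float, float]) -> float:
    mu, sd = stats
    return (value - mu) / sd if sd > 0 else 0.0


def filter_differential_peaks(
    peaks: list[PeakRecord],
    fc_threshold: float = FC_THRESHOLD_DEFAULT,
    p_threshold: float = P_THRESHOLD_DEFAULT,
) -> tuple[list[PeakRecord], int, int]:
    """Keep differential peaks: |log2 FC| >= log2(threshold), p < threshold.

    Both directions count, mirroring the upstream report of up- and
    down-regulated peaks. Returns (retained peaks, n_up, n_down).
    """
    log2_cut = math.log2(fc_threshold)
    retained, n_up, n_down = [], 0, 0
    for p in peaks:
        if p.log2_fc is None or p.p_value is None:
            raise ValueError(
                f"peak {p.chrom}:{p.start}-{p.end} ({p.gene_id}) lacks "
                "differential statistics (log2_fc, p_value)"
            )
        if abs(p.log2_fc) >= log2_cut and p.p_value < p_threshold:
            retained.append(p)
            if p.log2_fc > 0:
                n_up += 1
            elif p.log2_fc < 0:
                n_down += 1
    return retained, n_up, n_down
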