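"""Readers and writers for every on-disk artifact.

Formats are deliberately plain: whitespace/tab-separated tables with
optional ``#`` comment headers, one-symbol-per-line gene lists, and a flat
YAML run configuration. Gene identifiers are upper-cased, whitespace-
stripped symbols throughout; cross-database identifier harmonization is
the caller's responsibility.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml

logger = logging.getLogger("gatmerip")

SCORE_COLUMNS = ("gene_id", "raw_score", "minmax_score", "z_score", "rank")
FEATURE_COLUMNS = (
    "gene_id",
    "dataset_id",
    "expression_rpm",
    "m5c_rpm",
    "expression_z",
    "m5c_z",
    "label",
)


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeakRecord:
    """One called m5C peak assigned to a gene.

    Coordinates are BED-style: 0-based, half-open. ``m5c_rpm`` is the
    reads-per-million enrichment of the peak; ``log2_fc``/``p_value`` carry
    the differential statistics when a paired comparison was run upstream.
    """

    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str
    m5c_rpm: float
    log2_fc: float | None = None
    p_value: float | None = None
    dataset_id: str = ""

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(
                f"peak {self.chrom}:{self.start}-{self.end}: start must be < end"
            )
        if self.m5c_rpm < 0:
            raise ValueError(f"peak on {self.gene_id}: m5c_rpm must be >= 0")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"peak on {self.gene_id}: bad strand {self.strand!r}")
        if self.p_value is not None and not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"peak on {self.gene_id}: p_value outside [0, 1]")


@dataclass(frozen=True)
class ExpressionRecord:
    """RPM-normalized expression level of one gene in one dataset."""

    gene_id: str
    expression_rpm: float
    dataset_id: str = ""

    def __post_init__(self):
        if self.expression_rpm < 0:
            raise ValueError(f"{self.gene_id}: expression_rpm must be >= 0")


@dataclass(frozen=True)
class EdgeListRecord:
    """One protein-protein interaction line from a source database."""

    gene_a: str
    gene_b: str
    source: str = "ppi"


@dataclass
class ReadReport:
    """Audit trail of a read: nothing is dropped silently."""

    n_read: int = 0
    n_dropped: int = 0
    messages: list[str] = field(default_factory=list)


def _clean_symbol(raw: str) -> str:
    return raw.strip().upper()


# ---------------------------------------------------------------------------
# PPI edge lists
# ---------------------------------------------------------------------------

def read_edge_list(
    path: str | Path,
    format: str = "tsv",
    source: str | None = None,
    report: ReadReport | None = None,
) -> list[EdgeListRecord]:
    """Read a PPI edge list into records.

    ``format="tsv"``: 2-3 whitespace/tab-separated columns
    (gene_a, gene_b[, source]); ``#`` lines are comments.
    ``format="biogrid-tab"``: BioGRID tab3 export; official symbol columns
    are located by name in the header, falling back to columns 8/9.

    Self-interactions are dropped with a warning (structural self-loops are
    the model layer's job). Duplicate lines are kept: deduplication happens
    when the network is built.
    """
    path = Path(path)
    if format not in {"tsv", "biogrid-tab"}:
        raise ValueError(f"unknown edge-list format {format!r}")
    lines = path.read_text().splitlines()
    records: list[EdgeListRecord] = []
    rep = report if report is not None else ReadReport()

    col_a, col_b = 0, 1
    if format == "biogrid-tab":
        col_a, col_b = 7, 8  # tab3 default positions of official symbols
        for line in lines:
            if line.startswith("#"):
                headers = [h.strip().upper() for h in line.lstrip("#").split("\t")]
                for i, h in enumerate(headers):
                    if "OFFICIAL SYMBOL INTERACTOR A" in h:
                        col_a = i
                    elif "OFFICIAL SYMBOL INTERACTOR B" in h:
                        col_b = i
                break

    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) <= max(col_a, col_b):
            raise ValueError(
                f"{path}:{lineno}: expected at least {max(col_a, col_b) + 1} "
                f"columns, got {len(parts)}"
            )
        a, b = _clean_symbol(parts[col_a]), _clean_symbol(parts[col_b])
        if not a or not b:
            raise ValueError(f"{path}:{lineno}: empty gene symbol")
        rep.n_read += 1
        if a == b:
            rep.n_dropped += 1
            msg = f"{path}:{lineno}: self-interaction {a}-{b} dropped"
            rep.messages.append(msg)
            logger.warning(msg)
            continue
        src = source
        if src is None:
            src = parts[2].strip() if (format == "tsv" and len(parts) >= 3) else "ppi"
        records.append(EdgeListRecord(a, b, src))
    if rep.n_read == 0:
        raise ValueError(f"{path}: no interaction lines found")
    return records


# ---------------------------------------------------------------------------
# Peak / expression quantification tables
# ---------------------------------------------------------------------------

_PEAK_FIELDS = ("chrom", "start", "end", "gene_id", "m5c_rpm", "strand",
                "log2_fc", "p_value")


def read_quantification(
    peaks_path: str | Path,
    expression_path: str | Path,
    dataset_id: str,
    report: ReadReport | None = None,
) -> tuple[list[PeakRecord], list[ExpressionRecord]]:
    """Read one dataset's peak table and expression table.

    The peak table is BED6+2-style: chrom, start, end, name (gene symbol),
    score (m5C RPM), strand, then optionally log2 fold-change and p-value.
    A ``#``-prefixed header naming these columns may reorder them. The
    expression table has two columns: gene_id, expression_rpm.

    Rows violating the record invariants (start >= end, negative RPM,
    p-value outside [0, 1]) are rejected with an error naming the line.
    """
    peaks_path, expression_path = Path(peaks_path), Path(expression_path)
    rep = report if report is not None else ReadReport()

    order = list(_PEAK_FIELDS)
    peak_lines = peaks_path.read_text().splitlines()
    for line in peak_lines:
        if line.startswith("#"):
            names = [h.strip().lower() for h in line.lstrip("#").split("\t")]
            if set(names) & set(_PEAK_FIELDS):  # a schema header, not a comment
                missing = [c for c in _PEAK_FIELDS[:6] if c not in names]
                if missing:
                    raise ValueError(
                        f"{peaks_path}: header missing required columns "
                        f"{missing}; expected schema {list(_PEAK_FIELDS)}"
                    )
                order = names
            break

    peaks: list[PeakRecord] = []
    for lineno, line in enumerate(peak_lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 6:
            raise ValueError(
                f"{peaks_path}:{lineno}: expected >= 6 columns "
                f"(schema {list(_PEAK_FIELDS)}), got {len(parts)}"
            )
        row = dict(zip(order, parts))
        try:
            peaks.append(
                PeakRecord(
                    chrom=row["chrom"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    strand=row["strand"],
                    gene_id=_clean_symbol(row["gene_id"]),
                    m5c_rpm=float(row["m5c_rpm"]),
                    log2_fc=_opt_float(row.get("log2_fc")),
                    p_value=_opt_float(row.get("p_value")),
                    dataset_id=dataset_id,
                )
            )
        except (KeyError, ValueError) as exc:
            raise ValueError(f"{peaks_path}:{lineno}: {exc}") from exc
        rep.n_read += 1

    expression: list[ExpressionRecord] = []
    for lineno, line in enumerate(expression_path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 2:
            raise ValueError(
                f"{expression_path}:{lineno}: expected columns "
                "(gene_id, expression_rpm)"
            )
        try:
            expression.append(
                ExpressionRecord(_clean_symbol(parts[0]), float(parts[1]), dataset_id)
            )
        except ValueError as exc:
            raise ValueError(f"{expression_path}:{lineno}: {exc}") from exc
        rep.n_read += 1
    return peaks, expression


def _opt_float(raw: str | None) -> float | None:
    if raw is None:
        return None
    raw = raw.strip()
    if raw in {"", ".", "NA", "nan"}:
        return None
    value = float(raw)
    return None if math.isnan(value) else value


# ---------------------------------------------------------------------------
# Gene lists
# ---------------------------------------------------------------------------

def read_gene_list(path: str | Path) -> list[str]:
    """One symbol per line; ``#`` comments and blank lines skipped."""
    genes: list[str] = []
    seen: set[str] = set()
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        sym = _clean_symbol(line)
        if sym not in seen:
            seen.add(sym)
            genes.append(sym)
    return genes


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


# ---------------------------------------------------------------------------
# Score tables
# ---------------------------------------------------------------------------

def write_score_table(scores, path: str | Path) -> None:
    """Write a ScoreTable as TSV, ranked by descending raw score.

    Ties break lexicographically on gene_id, floats carry 6 decimals and
    ranks are 1-based, so output bytes are deterministic.
    """
    rows = scores.sorted_rows()
    if not rows:
        raise ValueError("refusing to write an empty score table")
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(SCORE_COLUMNS) + "\n")
        for row in rows:
            fh.write(
                f"{row.gene_id}\t{row.raw_score:.6f}\t{row.minmax_score:.6f}"
                f"\t{row.z_score:.6f}\t{row.rank}\n"
            )


def read_score_table(path: str | Path):
    from .training import ScoreRow, ScoreTable  # local import: avoid cycle

    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 5:
            raise ValueError(f"{path}:{lineno}: expected 5 columns")
        rows.append(
            ScoreRow(
                gene_id=parts[0],
                raw_score=float(parts[1]),
                minmax_score=float(parts[2]),
                z_score=float(parts[3]),
                rank=int(parts[4]),
            )
        )
    if not rows:
        raise ValueError(f"{path}: empty score table")
    return ScoreTable(rows)


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

def write_feature_table(features, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(FEATURE_COLUMNS) + "\n")
        for f in features:
            fh.write(
                f"{f.gene_id}\t{f.dataset_id}\t{f.expression_rpm:.6f}"
                f"\t{f.m5c_rpm:.6f}\t{f.expression_z:.6f}\t{f.m5c_z:.6f}"
                f"\t{f.label}\n"
            )


def read_feature_table(path: str | Path):
    from .features import GeneFeature  # local import: avoid cycle

    feats = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 7:
            raise ValueError(f"{path}:{lineno}: expected 7 columns")
        feats.append(
            GeneFeature(
                gene_id=parts[0],
                dataset_id=parts[1],
                expression_rpm=float(parts[2]),
                m5c_rpm=float(parts[3]),
                expression_z=float(parts[4]),
                m5c_z=float(parts[5]),
                label=int(parts[6]),
            )
        )
    return feats


# ---------------------------------------------------------------------------
# Run configuration (flat YAML)
# ---------------------------------------------------------------------------

def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a flat key-value mapping")
    return cfg


def write_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
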