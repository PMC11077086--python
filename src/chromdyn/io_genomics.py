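"""Readers/writers for interval, gene-model and matrix formats.

All coordinates are 0-based half-open (BED convention) internally; 1-based
inputs must be converted at the boundary by their readers.  Missing values
are serialized as ``NA``.  Chromosome names are compared by exact string
match — no ``chr`` aliasing unless explicitly enabled downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

MARKS = ("H3K4me1", "H3K4me3", "H3K27me3", "H3K27ac")

NA_REP = "NA"


class FormatError(ValueError):
    """Raised for malformed input files; message names the offending line."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval.

    ``start < end`` and ``start >= 0`` are enforced at construction so no
    downstream operation ever observes a degenerate interval.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"start must be < end, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be one of '+', '-', '.', got {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def distance(self, other: "GenomicInterval") -> int | None:
        """Gap between two intervals (0 if overlapping/bookended), None across chromosomes."""
        if self.chrom != other.chrom:
            return None
        if self.start < other.end and other.start < self.end:
            return 0
        return max(self.start, other.start) - min(self.end, other.end)


@dataclass(frozen=True)
class Peak:
    """A called peak for one histone mark at one time point (dpci)."""

    interval: GenomicInterval
    mark: str
    timepoint: int
    name: str = ""
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.mark not in MARKS:
            raise ValueError(f"unknown mark {self.mark!r}; expected one of {MARKS}")

    @property
    def width(self) -> int:
        return self.interval.width


@dataclass(frozen=True)
class GeneModel:
    """Gene model with strand-aware TSS and sorted, non-overlapping exons."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[GenomicInterval, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start >= end")
        exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
        object.__setattr__(self, "exons", tuple(exons))

    @property
    def tss(self) -> int:
        """Transcription start site: span start on '+', span end on '-'."""
        return self.start if self.strand == "+" else self.end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def length_bp(self) -> int:
        if self.exons:
            return sum(e.width for e in self.exons)
        return self.end - self.start


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 into validated intervals, preserving input order.

    Lines starting with ``#``, ``track`` or ``browser`` are ignored.
    Malformed lines raise :class:`FormatError` naming the line number.
    """
    path = Path(path)
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
            try:
                out.append(GenomicInterval(chrom, start, end, strand))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read a TSV gene table into gene models.

    Expected columns: gene_id, chrom, start, end, strand and optionally
    exon_starts / exon_ends (comma-separated, 0-based half-open).
    Duplicate gene_ids are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    required = {"gene_id", "chrom", "start", "end", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    dupes = df["gene_id"][df["gene_id"].duplicated()]
    if len(dupes):
        raise FormatError(f"{path}: duplicated gene_id(s): {sorted(set(dupes))}")
    genes: list[GeneModel] = []
    has_exons = "exon_starts" in df.columns and "exon_ends" in df.columns
    for row in df.itertuples(index=False):
        exons: tuple[GenomicInterval, ...] = ()
        if has_exons and isinstance(row.exon_starts, str) and row.exon_starts:
            starts = [int(x) for x in str(row.exon_starts).rstrip(",").split(",")]
            ends = [int(x) for x in str(row.exon_ends).rstrip(",").split(",")]
            if len(starts) != len(ends):
                raise FormatError(f"{path}: gene {row.gene_id}: exon_starts/ends length mismatch")
            exons = tuple(
                GenomicInterval(row.chrom, s, e, row.strand) for s, e in zip(starts, ends)
            )
        genes.append(
            GeneModel(
                gene_id=row.gene_id,
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                strand=str(row.strand),
                exons=exons,
            )
        )
    return genes


def write_gene_table(genes: Sequence[GeneModel], path: str | Path) -> None:
    rows = []
    for g in genes:
        rows.append(
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "exon_starts": ",".join(str(e.start) for e in g.exons),
                "exon_ends": ",".join(str(e.end) for e in g.exons),
            }
        )
    write_table(pd.DataFrame(rows, columns=[
        "gene_id", "chrom", "start", "end", "strand", "exon_starts", "exon_ends"
    ]), path)


# ---------------------------------------------------------------------------
# generic tables
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a TSV with deterministic column order and NA for missing values.

    Round-trips bit-identically through :func:`read_table` for string/float
    payloads; NaN is serialized as ``NA`` and read back as missing.
    """
    df.to_csv(path, sep="\t", na_rep=NA_REP, index=index, lineterminator="\n")


def read_table(path: str | Path, index_col: int | str | None = None) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", na_values=[NA_REP], keep_default_na=False, index_col=index_col
    )


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    """Write a region×column matrix, index (region_id) included."""
    df = df.copy()
    df.index.name = df.index.name or "region_id"
    df.to_csv(path, sep="\t", na_rep=NA_REP, lineterminator="\n")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA_REP], keep_default_na=False, index_col=0)
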