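"""Peak merging, promoter/genebody/intergenic annotation and enrichment
normalization.

Regions are the unit of all downstream analyses: per-mark, per-timepoint
peaks are pooled and merged (gap <= 100 bp by default, matching
``bedtools merge -d 100`` semantics), quantified as RPKM and normalized per
column as the z-score of log2(RPKM + 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_genomics import GeneModel, GenomicInterval

PROMOTER_WINDOW = 2000  # TSS +/- 2 kb


@dataclass
class EnrichmentMatrix:
    """Regions × (mark, timepoint) signal table with raw and normalized layers.

    ``raw`` holds RPKM values (>= 0); ``norm`` holds the per-column z-score of
    log2(raw + 1).  Columns are named ``{mark}_{timepoint}``.
    ``degenerate_columns`` lists zero-variance columns whose z-scores were
    set to zero.
    """

    raw: pd.DataFrame
    norm: pd.DataFrame
    marks: tuple[str, ...]
    timepoints: tuple[int, ...]
    degenerate_columns: tuple[str, ...] = ()

    @classmethod
    def from_raw(
        cls,
        raw: pd.DataFrame,
        marks: Sequence[str],
        timepoints: Sequence[int],
        ddof: int = 1,
    ) -> "EnrichmentMatrix":
        if (raw.values < 0).any():
            raise ValueError("raw RPKM values must be >= 0")
        norm, degenerate = normalize_z_log2(raw, ddof=ddof)
        return cls(
            raw=raw,
            norm=norm,
            marks=tuple(marks),
            timepoints=tuple(timepoints),
            degenerate_columns=tuple(degenerate),
        )

    @property
    def region_ids(self) -> pd.Index:
        return self.raw.index

    def column(self, mark: str, timepoint: int) -> str:
        return f"{mark}_{timepoint}"

    def mark_profile(self, mark: str, layer: str = "norm") -> pd.DataFrame:
        """Region × timepoint table for one mark."""
        df = self.norm if layer == "norm" else self.raw
        cols = [self.column(mark, tp) for tp in self.timepoints]
        out = df[cols].copy()
        out.columns = list(self.timepoints)
        return out


@dataclass(frozen=True)
class RegionAnnotation:
    region_id: str
    category: str  # promoter | genebody | intergenic
    gene_id: str | None
    distance_to_tss: int | None  # signed bp, gap distance; + downstream in genomic coords


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

def merge_peaks(
    peak_sets: Iterable[Iterable[GenomicInterval]] | Iterable[GenomicInterval],
    gap: int = 100,
) -> list[GenomicInterval]:
    """Merge peaks across sets; intervals closer than ``gap`` bp chain together.

    Follows ``bedtools merge -d gap``: two intervals merge when the distance
    between them (bases strictly between, 0 if touching or overlapping) is
    <= gap.  Output is sorted; intervals on different chromosomes never merge.
    Idempotent: merging merged output changes nothing.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    flat: list[GenomicInterval] = []
    for item in peak_sets:
        if isinstance(item, GenomicInterval):
            flat.append(item)
        else:
            flat.extend(item)
    if not flat:
        return []
    flat.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    cur_chrom, cur_start, cur_end = flat[0].chrom, flat[0].start, flat[0].end
    for iv in flat[1:]:
        if iv.chrom == cur_chrom and iv.start - cur_end <= gap:
            cur_end = max(cur_end, iv.end)
        else:
            merged.append(GenomicInterval(cur_chrom, cur_start, cur_end))
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
    merged.append(GenomicInterval(cur_chrom, cur_start, cur_end))
    return merged


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

class GeneIndex:
    """Sorted per-chromosome index over gene TSSs and spans for fast queries."""

    def __init__(self, genes: Sequence[GeneModel]):
        self.genes = list(genes)
        self._by_chrom: dict[str, list[tuple[int, GeneModel]]] = {}
        for g in genes:
            self._by_chrom.setdefault(g.chrom, []).append((g.tss, g))
        for entries in self._by_chrom.values():
            entries.sort(key=lambda t: (t[0], t[1].gene_id))

    def nearest_tss(self, region: GenomicInterval) -> tuple[GeneModel, int] | None:
        """Nearest gene by TSS gap distance; ties broken by smallest gene_id.

        Distance is signed: 0 when the region contains the TSS, positive when
        the region lies downstream of the TSS (higher coordinates), negative
        upstream.
        """
        entries = self._by_chrom.get(region.chrom)
        if not entries:
            return None
        best: tuple[int, str, GeneModel, int] | None = None
        for tss, g in entries:
            if region.start <= tss < region.end:
                signed = 0
            elif tss >= region.end:
                signed = -(tss - (region.end - 1))  # region upstream of TSS
            else:
                signed = region.start - tss  # region downstream of TSS
            key = (abs(signed), g.gene_id)
            if best is None or key < (best[0], best[1]):
                best = (abs(signed), g.gene_id, g, signed)
        assert best is not None
        return best[2], best[3]

    def overlapping_span(self, region: GenomicInterval) -> list[GeneModel]:
        entries = self._by_chrom.get(region.chrom, [])
        return [g for _, g in entries if g.span.overlaps(region)]


def annotate_region(
    region: GenomicInterval,
    index: GeneIndex,
    region_id: str = "",
    promoter_window: int = PROMOTER_WINDOW,
    rule: str = "overlap",
) -> RegionAnnotation:
    """Assign a region to promoter / genebody / intergenic.

    Priority: promoter > genebody > intergenic.  With the default ``overlap``
    rule a region is a promoter when it overlaps [TSS - w, TSS + w) of the
    nearest TSS (equivalently, its gap distance to the TSS is <= w); the
    ``midpoint`` rule instead requires the region midpoint inside the window.
    Genebody: any overlap with a gene span, assigned to the nearest TSS.
    """
    hit = index.nearest_tss(region)
    if hit is None:
        return RegionAnnotation(region_id, "intergenic", None, None)
    gene, signed = hit
    if rule == "midpoint":
        mid = (region.start + region.end) // 2
        is_promoter = abs(mid - gene.tss) <= promoter_window
    else:
        is_promoter = abs(signed) <= promoter_window
    if is_promoter:
        return RegionAnnotation(region_id, "promoter", gene.gene_id, signed)
    spanning = index.overlapping_span(region)
    if spanning:
        body_gene = min(spanning, key=lambda g: g.gene_id)
        # keep nearest-TSS assignment when that gene's span also overlaps
        if any(g.gene_id == gene.gene_id for g in spanning):
            body_gene = gene
        return RegionAnnotation(region_id, "genebody", body_gene.gene_id, signed)
    return RegionAnnotation(region_id, "intergenic", None, signed)


def annotate_regions(
    regions: Mapping[str, GenomicInterval] | Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    promoter_window: int = PROMOTER_WINDOW,
    rule: str = "overlap",
) -> pd.DataFrame:
    index = GeneIndex(genes)
    if isinstance(regions, Mapping):
        items = list(regions.items())
    else:
        items = [(f"region_{i}", r) for i, r in enumerate(regions)]
    rows = []
    for rid, region in items:
        ann = annotate_region(region, index, rid, promoter_window, rule)
        rows.append(
            {
                "region_id": rid,
                "category": ann.category,
                "gene_id": ann.gene_id,
                "distance_to_tss": ann.distance_to_tss,
            }
        )
    columns = ["region_id", "category", "gene_id", "distance_to_tss"]
    return pd.DataFrame(rows, columns=columns).set_index("region_id")


# ---------------------------------------------------------------------------
# quantification / normalization
# ---------------------------------------------------------------------------

def quantify_rpkm(
    counts: pd.DataFrame,
    region_lengths_bp: pd.Series | np.ndarray,
    library_sizes: pd.Series | Mapping[str, float] | np.ndarray,
) -> pd.DataFrame:
    """RPKM = count / (length_kb * mapped_millions), per column (sample)."""
    counts = counts.astype(float)
    lengths = np.asarray(
        region_lengths_bp.reindex(counts.index)
        if isinstance(region_lengths_bp, pd.Series)
        else region_lengths_bp,
        dtype=float,
    )
    if (counts.values < 0).any():
        raise ValueError("counts must be >= 0")
    if (lengths <= 0).any() or np.isnan(lengths).any():
        raise ValueError("region lengths must be > 0")
    if isinstance(library_sizes, Mapping):
        libs = np.array([library_sizes[c] for c in counts.columns], dtype=float)
    elif isinstance(library_sizes, pd.Series):
        libs = library_sizes.reindex(counts.columns).to_numpy(dtype=float)
    else:
        libs = np.asarray(library_sizes, dtype=float)
    if (libs <= 0).any() or np.isnan(libs).any():
        raise ValueError("library sizes must be > 0")
    rpkm = counts.values / (lengths[:, None] / 1e3) / (libs[None, :] / 1e6)
    return pd.DataFrame(rpkm, index=counts.index, columns=counts.columns)


def normalize_z_log2(
    raw: pd.DataFrame, ddof: int = 1
) -> tuple[pd.DataFrame, list[str]]:
    """Per-column z-score of log2(x + 1).

    ``ddof=1`` (sample sd, the R ``scale()`` convention) is the default;
    ``ddof=0`` selects the population sd.  Zero-variance columns yield an
    all-zero column and are reported in the returned flag list.
    """
    if not np.isfinite(raw.values).all():
        raise ValueError("raw values must be finite")
    logged = np.log2(raw.astype(float) + 1.0)
    mean = logged.mean(axis=0)
    sd = logged.std(axis=0, ddof=ddof)
    degenerate = [c for c in logged.columns if not np.isfinite(sd[c]) or sd[c] == 0.0]
    sd_safe = sd.replace(0.0, np.nan)
    z = (logged - mean) / sd_safe
    for c in degenerate:
        z[c] = 0.0
    return z, degenerate


def marked_gene_fraction(
    genes: Sequence[GeneModel], annotations: pd.DataFrame
) -> float:
    """Fraction of genes with >= 1 peak annotated to them (promoter or genebody)."""
    if len(genes) == 0:
        raise ValueError("zero genes")
    marked = set(
        annotations.loc[
            annotations["category"].isin(["promoter", "genebody"]), "gene_id"
        ].dropna()
    )
    return sum(1 for g in genes if g.gene_id in marked) / len(genes)
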