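"""Promoter windows and per-gene euchromatinization calls from ChIP intervals.

A gene's promoter is the ``upstream_bp`` window immediately 5' of its
transcription start site (default 1000 bp, i.e. -1000..0 relative to the
TSS), half-open and excluding the TSS base itself, clipped at the
chromosome origin.  A promoter is called "euchromatinized" in a cell
line when any treated-condition ChIP-enriched region overlaps it by at
least ``min_overlap_bp``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import DataValidationError, GeneAnnotation, RegionSet


@dataclass(frozen=True)
class PromoterWindow:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str


def promoter_windows(annotation: GeneAnnotation, upstream_bp: int = 1000) -> list[PromoterWindow]:
    """Strand-aware upstream windows: + strand [TSS-u, TSS); - strand [TSS, TSS+u).

    The TSS is the gene start on + and the gene end on -.  Windows are
    clipped at coordinate 0 and never overlap the gene body.
    """
    if upstream_bp <= 0:
        raise ValueError("upstream_bp must be positive")
    out = []
    for gene_id, row in annotation.table.iterrows():
        if row.strand == "+":
            tss = int(row.start)
            start, end = max(0, tss - upstream_bp), tss
        else:
            tss = int(row.end)
            start, end = tss, tss + upstream_bp
        if start < end:
            out.append(PromoterWindow(gene_id, str(row.chrom), start, end, row.strand))
        else:  # + strand gene starting at 0: empty window, keep a zero-width record out
            out.append(PromoterWindow(gene_id, str(row.chrom), 0, 0, row.strand))
    return out


def promoters_to_bed(promoters: list[PromoterWindow]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.chrom, p.start, p.end, p.gene_id, 0, p.strand) for p in promoters],
        columns=["chrom", "start", "end", "name", "score", "strand"],
    )


def overlap_calls(
    promoters: list[PromoterWindow], regions: RegionSet, min_overlap_bp: int = 1
) -> dict[str, bool]:
    """True per gene iff some region overlaps its promoter by >= min_overlap_bp.

    Half-open semantics: touching intervals ([a,b) and [b,c)) do not overlap.
    Implementation sorts regions by start per chromosome and narrows the
    candidate window by binary search plus a running maximum of region ends,
    then verifies the overlap length exactly on the surviving slice.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    prom_chroms = {p.chrom for p in promoters}
    for chrom, grp in regions.intervals.groupby("chrom", sort=False):
        if chrom not in prom_chroms:
            warnings.warn(
                f"regions on chromosome {chrom!r} have no annotated genes; ignored",
                stacklevel=2,
            )
            continue
        starts = grp["start"].to_numpy(np.int64)
        ends = grp["end"].to_numpy(np.int64)
        order = np.argsort(starts, kind="stable")
        starts, ends = starts[order], ends[order]
        by_chrom[chrom] = (starts, ends, np.maximum.accumulate(ends))
    calls: dict[str, bool] = {}
    for p in promoters:
        hit = False
        if p.end - p.start >= min_overlap_bp and p.chrom in by_chrom:
            starts, ends, maxend = by_chrom[p.chrom]
            # candidate regions must start early enough to reach min_overlap
            j = np.searchsorted(starts, p.end - min_overlap_bp, side="right")
            if j > 0 and maxend[j - 1] >= p.start + min_overlap_bp:
                ov = np.minimum(ends[:j], p.end) - np.maximum(starts[:j], p.start)
                hit = bool((ov >= min_overlap_bp).any())
        calls[p.gene_id] = hit
    return calls


def euchromatinization_matrix(
    region_sets: dict[str, RegionSet],
    annotation: GeneAnnotation,
    upstream_bp: int = 1000,
    min_overlap_bp: int = 1,
) -> pd.DataFrame:
    """Boolean genes x cell-lines matrix of promoter euchromatinization calls.

    ``region_sets`` maps cell line -> treated-condition enriched regions
    (differential region calling itself is produced upstream and consumed
    here as BED input).
    """
    if len(set(region_sets)) != len(region_sets):
        raise DataValidationError("duplicate cell line in region sets")
    promoters = promoter_windows(annotation, upstream_bp=upstream_bp)
    cols = {}
    for line, rs in region_sets.items():
        calls = overlap_calls(promoters, rs, min_overlap_bp=min_overlap_bp)
        cols[line] = [calls[g] for g in annotation.gene_ids]
    return pd.DataFrame(cols, index=annotation.gene_ids)
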