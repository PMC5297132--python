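"""Segmentation of the P-value track into differential nucleosome regions.

Candidate regions are maximal runs of bases with P strictly below the cutoff
(default 1e-5). Candidates shorter than 10 bp are neglected, then adjacent
survivors closer than 5 bp are merged — in that order, and with strict
inequalities throughout. Each final region carries its boundaries, center,
minimum per-base P-value, and a Benjamini–Hochberg FDR computed over the
per-region representative P-values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .chi2test import LocusTestTrack

__all__ = [
    "DNR",
    "AnnotationScheme",
    "candidate_regions",
    "filter_and_merge",
    "finalize_dnrs",
    "attach_fdr",
    "call_dnrs",
    "annotate_dnrs",
    "DEFAULT_CUTOFF",
    "DEFAULT_MIN_LEN",
    "DEFAULT_MERGE_GAP",
]

DEFAULT_CUTOFF = 1e-5
DEFAULT_MIN_LEN = 10
DEFAULT_MERGE_GAP = 5


@dataclass(frozen=True)
class DNR:
    chrom: str
    start: int
    end: int
    center: int
    p_value: float
    fdr: float
    id: str


@dataclass
class AnnotationScheme:
    """TSS table plus the strand-oriented promoter window.

    ``tss_table`` needs columns chrom, tss, strand, gene_id; the promoter is
    upstream_bp before to downstream_bp after the TSS (defaults -500/+300).
    """

    tss_table: pd.DataFrame
    upstream_bp: int = 500
    downstream_bp: int = 300

    def __post_init__(self) -> None:
        if -self.upstream_bp >= self.downstream_bp:
            raise ValueError("promoter window upstream bound must precede downstream bound")
        missing = {"chrom", "tss", "strand", "gene_id"} - set(self.tss_table.columns)
        if missing:
            raise ValueError(f"TSS table lacks columns: {sorted(missing)}")


def _check_sorted_disjoint(intervals: Sequence[tuple[int, int]]) -> None:
    prev_end = None
    for s, e in intervals:
        if s >= e:
            raise ValueError(f"empty or inverted interval [{s}, {e})")
        if prev_end is not None and s < prev_end:
            raise ValueError("intervals must be sorted and non-overlapping")
        prev_end = e


def candidate_regions(
    track: LocusTestTrack, cutoff: float = DEFAULT_CUTOFF
) -> list[tuple[int, int]]:
    """Maximal runs of consecutive bases with P < cutoff (strict)."""
    if not (0 < cutoff <= 1):
        raise ValueError("cutoff must be in (0, 1]")
    mask = track.pvalue < cutoff
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    starts, ends = edges[0::2], edges[1::2]
    return list(zip(starts.tolist(), ends.tolist()))


def filter_and_merge(
    candidates: Sequence[tuple[int, int]],
    min_len: int = DEFAULT_MIN_LEN,
    merge_gap: int = DEFAULT_MERGE_GAP,
) -> list[tuple[int, int]]:
    """Drop candidates shorter than ``min_len``, then merge adjacent
    survivors whose gap is strictly less than ``merge_gap``.

    The order matters (a short candidate never rescues a merge) and both
    comparisons are strict: length exactly ``min_len`` is kept, a gap of
    exactly ``merge_gap`` is not merged.
    """
    _check_sorted_disjoint(candidates)
    kept = [(s, e) for s, e in candidates if e - s >= min_len]
    merged: list[tuple[int, int]] = []
    for s, e in kept:
        if merged and s - merged[-1][1] < merge_gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def finalize_dnrs(
    intervals: Sequence[tuple[int, int]], track: LocusTestTrack
) -> list[DNR]:
    """Attach center, representative P (per-base minimum) and BH FDR."""
    dnrs: list[DNR] = []
    for k, (s, e) in enumerate(intervals, start=1):
        if s < 0 or e > len(track):
            raise ValueError(f"interval [{s}, {e}) outside track of length {len(track)}")
        p = float(track.pvalue[s:e].min())
        dnrs.append(
            DNR(
                chrom=track.chrom,
                start=int(s),
                end=int(e),
                center=(int(s) + int(e)) // 2,
                p_value=p,
                fdr=float("nan"),
                id=f"DNR_{track.chrom}_{k}",
            )
        )
    return attach_fdr(dnrs)


def attach_fdr(dnrs: Sequence[DNR]) -> list[DNR]:
    """Benjamini–Hochberg adjustment over the per-DNR representative
    P-values; monotone in P and invariant to input order."""
    if not dnrs:
        return []
    pvals = np.array([d.p_value for d in dnrs])
    fdr = multipletests(pvals, method="fdr_bh")[1]
    return [replace(d, fdr=float(q)) for d, q in zip(dnrs, fdr)]


def call_dnrs(
    track: LocusTestTrack,
    cutoff: float = DEFAULT_CUTOFF,
    min_len: int = DEFAULT_MIN_LEN,
    merge_gap: int = DEFAULT_MERGE_GAP,
) -> list[DNR]:
    """End-to-end calling: candidates -> filter/merge -> finalized DNRs."""
    return finalize_dnrs(
        filter_and_merge(candidate_regions(track, cutoff), min_len, merge_gap), track
    )


def annotate_dnrs(
    dnrs: Sequence[DNR],
    scheme: AnnotationScheme,
    gene_spans: pd.DataFrame,
) -> tuple[list[str], pd.DataFrame]:
    """Classify each DNR center as promoter, intragenic or intergenic.

    Promoter: within the strand-oriented window [TSS - upstream, TSS +
    downstream] of any gene. Intragenic: between the downstream promoter edge
    and the transcription termination site. Anything else is intergenic;
    precedence is promoter > intragenic > intergenic. ``gene_spans`` needs
    columns chrom, start, end (TTS = strand-oriented far end), strand,
    gene_id. Returns per-DNR categories plus a count/fraction summary table.
    """
    if not len(dnrs):
        summary = pd.DataFrame(
            {"category": ["promoter", "intragenic", "intergenic"], "count": 0, "fraction": 0.0}
        )
        return [], summary
    chroms = {d.chrom for d in dnrs}
    known = set(scheme.tss_table["chrom"].astype(str))
    missing = chroms - known
    if missing:
        raise ValueError(f"DNR chromosomes absent from annotation: {sorted(missing)}")

    tss = scheme.tss_table
    promoter_windows: dict[str, list[tuple[int, int]]] = {}
    intragenic_windows: dict[str, list[tuple[int, int]]] = {}
    spans = gene_spans.set_index("gene_id") if "gene_id" in gene_spans else None
    for row in tss.itertuples(index=False):
        if row.strand == "+":
            p_lo, p_hi = row.tss - scheme.upstream_bp, row.tss + scheme.downstream_bp
        else:
            p_lo, p_hi = row.tss - scheme.downstream_bp, row.tss + scheme.upstream_bp
        promoter_windows.setdefault(str(row.chrom), []).append((p_lo, p_hi))
        if spans is not None and row.gene_id in spans.index:
            g = spans.loc[row.gene_id]
            if row.strand == "+":
                lo, hi = row.tss + scheme.downstream_bp, int(g["end"])
            else:
                lo, hi = int(g["start"]), row.tss - scheme.downstream_bp
            if lo < hi:
                intragenic_windows.setdefault(str(row.chrom), []).append((lo, hi))

    categories: list[str] = []
    for d in dnrs:
        c = d.center
        if any(lo <= c <= hi for lo, hi in promoter_windows.get(d.chrom, [])):
            categories.append("promoter")
        elif any(lo <= c <= hi for lo, hi in intragenic_windows.get(d.chrom, [])):
            categories.append("intragenic")
        else:
            categories.append("intergenic")

    counts = pd.Series(categories).value_counts()
    summary = pd.DataFrame(
        {
            "category": ["promoter", "intragenic", "intergenic"],
            "count": [int(counts.get(c, 0)) for c in ("promoter", "intragenic", "intergenic")],
        }
    )
    summary["fraction"] = summary["count"] / len(dnrs)
    return categories, summary
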