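"""Projection of QTL regions onto reference-genome syntenic segments.

Syntenic segments — blocks of the cotton consensus map with a conserved
counterpart in a reference genome (Arabidopsis in the motivating study) —
arrive as an input table of cotton cM intervals tagged with reference block
ids.  A QTL region projects onto every segment whose cotton interval overlaps
the region's closed interval on the same chromosome (a shared boundary point
counts).  Reference gene annotations attached to the segments then yield, per
region, the orthologous stress-related gene list.  Because "associated with a
region" can reasonably mean either any overlap or full containment of the
segment, reports carry both counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

SEGMENT_COLUMNS = ["segment_id", "chromosome", "lo_cM", "hi_cM"]
GENE_COLUMNS = ["gene_id", "segment_id", "function_text", "stress_related"]


@dataclass(frozen=True)
class SegmentMatch:
    segment_id: str
    overlap_cM: float
    contained: bool


def project_region(region, segments: pd.DataFrame) -> list[SegmentMatch]:
    """Segments overlapping a region's closed interval on its chromosome.

    ``region`` needs attributes/keys ``chromosome, lo_cM, hi_cM``.  The
    reported overlap length is the length of the interval intersection (zero
    for a single shared boundary point, which still matches); ``contained``
    marks segments lying entirely inside the region.
    """
    chrom = int(region["chromosome"] if isinstance(region, (dict, pd.Series))
                else region.chromosome)
    lo = float(region["lo_cM"] if isinstance(region, (dict, pd.Series)) else region.lo_cM)
    hi = float(region["hi_cM"] if isinstance(region, (dict, pd.Series)) else region.hi_cM)
    matches = []
    for seg in segments.itertuples(index=False):
        if int(seg.chromosome) != chrom:
            continue
        s_lo, s_hi = float(seg.lo_cM), float(seg.hi_cM)
        if s_lo > hi or s_hi < lo:
            continue
        overlap = min(hi, s_hi) - max(lo, s_lo)
        matches.append(SegmentMatch(str(seg.segment_id), overlap,
                                    lo <= s_lo and s_hi <= hi))
    return matches


def syntenic_stress_genes(matches: list[SegmentMatch], genes: pd.DataFrame
                          ) -> pd.DataFrame:
    """Unique reference genes across matched segments, stress subset marked.

    A gene annotated in two matched segments is listed once (first segment in
    match order wins the attribution).  Output columns: ``gene_id,
    segment_id, function_text, stress_related, segment_contained``.
    """
    seen: dict[str, tuple] = {}
    by_segment = {seg: grp for seg, grp in genes.groupby("segment_id")} if not genes.empty else {}
    for match in matches:
        grp = by_segment.get(match.segment_id)
        if grp is None:
            continue
        for gene in grp.itertuples(index=False):
            if gene.gene_id not in seen:
                seen[gene.gene_id] = (gene.gene_id, match.segment_id,
                                      gene.function_text,
                                      bool(gene.stress_related), match.contained)
    return pd.DataFrame(
        seen.values(),
        columns=["gene_id", "segment_id", "function_text", "stress_related",
                 "segment_contained"],
    )


def region_synteny_report(regions: pd.DataFrame, segments: pd.DataFrame,
                          genes: pd.DataFrame) -> pd.DataFrame:
    """Per-region synteny report: segments, orthologous genes, functions.

    One row per (region, gene); regions without matched segments are omitted.
    The summary counts per region distinguish any-overlap genes from genes on
    fully contained segments.
    """
    rows = []
    for region in regions.itertuples(index=False):
        matches = project_region(region, segments)
        gene_table = syntenic_stress_genes(matches, genes)
        for g in gene_table.itertuples(index=False):
            rows.append((region.region_id, region.traits, region.chromosome,
                         g.segment_id, g.gene_id, g.function_text,
                         g.stress_related, g.segment_contained))
    return pd.DataFrame(rows, columns=["region_id", "traits", "chromosome",
                                       "segment_id", "gene_id",
                                       "function_text", "stress_related",
                                       "segment_contained"])


def synteny_summary(report: pd.DataFrame) -> dict[str, int]:
    """Overall stress-gene counts: any overlap vs fully contained segments."""
    if report.empty:
        return {"stress_genes_any_overlap": 0, "stress_genes_contained": 0}
    stress = report[report["stress_related"].astype(bool)]
    return {
        "stress_genes_any_overlap": int(stress["gene_id"].nunique()),
        "stress_genes_contained": int(
            stress.loc[stress["segment_contained"].astype(bool), "gene_id"].nunique()
        ),
    }


__all__ = ["SegmentMatch", "SEGMENT_COLUMNS", "GENE_COLUMNS", "project_region",
           "syntenic_stress_genes", "region_synteny_report", "synteny_summary"]
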