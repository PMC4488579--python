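"""QTL interval merging and transcript/QTL colocalization.

A QTL is a trait-linked 2-LOD (~99%) confidence interval on a consensus-map
chromosome, in centimorgans.  Overlapping or touching intervals on one
chromosome are unioned transitively into disjoint *QTL regions*; a mapped
transcript colocalizes with a region when one of its anchored loci falls
inside the region's closed interval.  Intervals are boundary-inclusive: a
locus printed at the exact edge of a confidence interval counts as inside.
"""

from __future__ import annotations

import pandas as pd

TRAIT_CODES = frozenset(
    {"OP", "d13C", "Chl-a", "Chl-b", "CT", "DM", "HI", "SC", "BW", "FF", "FS", "FL"}
)

QTL_COLUMNS = ["trait", "chromosome", "ci_lo_cM", "ci_hi_cM"]
REGION_COLUMNS = ["region_id", "chromosome", "lo_cM", "hi_cM", "traits", "n_qtls"]


def validate_qtls(qtls: pd.DataFrame) -> pd.DataFrame:
    """Check trait vocabulary and interval sanity; returns the frame unchanged."""
    for row in qtls.itertuples(index=False):
        for code in str(row.trait).split(","):
            if code.strip() not in TRAIT_CODES:
                raise ValueError(f"unknown trait code {code.strip()!r}")
        if row.ci_lo_cM > row.ci_hi_cM:
            raise ValueError(
                f"inverted interval on chromosome {row.chromosome}: "
                f"[{row.ci_lo_cM}, {row.ci_hi_cM}]"
            )
    return qtls


def merge_regions(qtls: pd.DataFrame) -> pd.DataFrame:
    """Union overlapping-or-touching QTL intervals per chromosome.

    Returns one row per region with columns ``region_id, chromosome, lo_cM,
    hi_cM, traits, n_qtls``; ``traits`` is the comma-joined sorted union of
    the member QTLs' trait codes.  Regions are sorted by chromosome then lo,
    ids ``R01``... in that order.  Idempotent: feeding the output back in (as
    one pseudo-QTL per region) reproduces the same intervals.
    """
    if qtls.empty:
        return pd.DataFrame(columns=REGION_COLUMNS)
    regions = []
    for chrom, grp in qtls.groupby("chromosome", sort=True):
        grp = grp.sort_values(["ci_lo_cM", "ci_hi_cM"], kind="mergesort")
        cur = None
        for row in grp.itertuples(index=False):
            traits = [t.strip() for t in str(row.trait).split(",")]
            if cur is not None and row.ci_lo_cM <= cur[2]:  # touching counts
                cur[2] = max(cur[2], float(row.ci_hi_cM))
                cur[3].update(traits)
                cur[4] += 1
            else:
                if cur is not None:
                    regions.append(cur)
                cur = [int(chrom), float(row.ci_lo_cM), float(row.ci_hi_cM),
                       set(traits), 1]
        regions.append(cur)
    out = pd.DataFrame(
        [(f"R{i + 1:02d}", c, lo, hi, ", ".join(sorted(tr)), n)
         for i, (c, lo, hi, tr, n) in enumerate(regions)],
        columns=REGION_COLUMNS,
    )
    return out


def colocalize(hits: pd.DataFrame, regions: pd.DataFrame,
               valid_chromosomes: set[int] | None = None
               ) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    """Assign anchored loci to QTL regions by closed-interval membership.

    ``hits`` is an anchoring table with at least ``tc_id, marker_id,
    chromosome, position_cM``.  Returns (assignments, per-region unique TC
    sets); a TC is *colocalized* when it has at least one assignment.  The
    global colocalized set is the deduplicated union over regions.  When
    ``valid_chromosomes`` (the map's chromosome set) is given, a locus on an
    unknown chromosome is an input error.
    """
    if valid_chromosomes is not None and not hits.empty:
        unknown = set(hits["chromosome"].astype(int)) - set(valid_chromosomes)
        if unknown:
            raise ValueError(f"loci on chromosomes absent from the map: {sorted(unknown)}")
    assignments = []
    per_region: dict[str, set[str]] = {r: set() for r in regions["region_id"]}
    for hit in hits.itertuples(index=False):
        sub = regions[(regions["chromosome"] == hit.chromosome)
                      & (regions["lo_cM"] <= hit.position_cM)
                      & (hit.position_cM <= regions["hi_cM"])]
        for reg in sub.itertuples(index=False):
            assignments.append((hit.tc_id, reg.region_id, hit.marker_id,
                                hit.chromosome, hit.position_cM))
            per_region[reg.region_id].add(hit.tc_id)
    out = pd.DataFrame(assignments, columns=["tc_id", "region_id", "marker_id",
                                             "chromosome", "position_cM"])
    return out, per_region


def colocalized_set(assignments: pd.DataFrame) -> set[str]:
    """Deduplicated set of colocalized TC ids across all regions and loci."""
    return set(assignments["tc_id"]) if not assignments.empty else set()


def region_table(regions: pd.DataFrame, per_region: dict[str, set[str]],
                 annotations: pd.DataFrame | None = None,
                 expression: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-region summary: traits, interval, unique TCs, stress-function, DE.

    A TC occupying two regions is counted once in each region's row; the
    deduplicated global count is the job of the enrichment contingency.
    ``annotations`` needs ``tc_id, function_label, stress_related``;
    ``expression`` needs ``transcript_id``.
    """
    stress_ids: set[str] = set()
    if annotations is not None and not annotations.empty:
        ann = annotations[annotations["function_label"].astype(str).str.len() > 0]
        stress_ids = set(ann.loc[ann["stress_related"].astype(bool), "tc_id"])
    de_ids: set[str] = set()
    if expression is not None and not expression.empty:
        de_ids = set(expression["transcript_id"])
    rows = []
    for reg in regions.itertuples(index=False):
        members = per_region.get(reg.region_id, set())
        rows.append((reg.region_id, reg.traits, reg.chromosome, reg.lo_cM,
                     reg.hi_cM, len(members), len(members & stress_ids),
                     len(members & de_ids)))
    return pd.DataFrame(rows, columns=["region_id", "traits", "chromosome",
                                       "lo_cM", "hi_cM", "n_tc",
                                       "n_stress_function", "n_de"])


__all__ = ["TRAIT_CODES", "QTL_COLUMNS", "REGION_COLUMNS", "validate_qtls",
           "merge_regions", "colocalize", "colocalized_set", "region_table"]
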