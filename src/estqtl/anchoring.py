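"""In-silico mapping of TCs onto a genetic map via homology to STS markers.

Each sequence-tagged site (STS) on the consensus genetic map carries a known
sequence and a cM position.  A tentative consensus sequence is anchored to a
locus when a gap-free local alignment to the marker sequence, in either
orientation, reaches 90% identity over at least 100 bp (defaults).  All
threshold-passing loci are retained for every TC — transcripts genuinely map
to multiple loci on a consensus map of a palaeopolyploid genome, and pruning
to a best hit would hide that signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from ._seqops import encode, exact_seed_length, revcomp, seed_diagonals
from .assembly import FORWARD, REVCOMP, _scan_offsets

logger = logging.getLogger(__name__)

HIT_COLUMNS = ["tc_id", "marker_id", "chromosome", "position_cM",
               "identity", "overlap_len", "orientation"]


@dataclass(frozen=True)
class AnchorParams:
    """Marker-homology acceptance thresholds for in-silico mapping."""

    min_identity: float = 0.90
    min_overlap_bp: int = 100
    seed_k: int = 11

    def __post_init__(self) -> None:
        if not (0 < self.min_identity <= 1):
            raise ValueError("min_identity must be in (0, 1]")
        if self.min_overlap_bp < 1:
            raise ValueError("min_overlap_bp must be >= 1")
        if not (1 <= self.seed_k <= self.min_overlap_bp):
            raise ValueError("seed_k must be in [1, min_overlap_bp]")

    @property
    def effective_seed_k(self) -> int:
        # Clamped so the diagonal seed filter can never drop a placement that
        # passes both thresholds.
        return min(self.seed_k, exact_seed_length(self.min_identity, self.min_overlap_bp))


@dataclass(frozen=True)
class AnchorHit:
    tc_id: str
    marker_id: str
    chromosome: int
    position_cM: float
    identity: float
    overlap_len: int
    orientation: str


@dataclass
class MappingStats:
    n_tc_mapped: int
    n_loci_hit: int
    n_loci_multi_tc: int
    n_tc_multi_locus: int


class _ScanParams:
    """Adapter exposing anchoring thresholds to the shared offset scanner."""

    def __init__(self, params: AnchorParams) -> None:
        self.min_identity = params.min_identity
        self.min_overlap_bp = params.min_overlap_bp


def _best_placement(etc, emk, params: AnchorParams, *, exhaustive: bool):
    """Best placement over both orientations of the TC against one marker.

    Selection among threshold-passing placements: highest identity, then
    longest overlap, then forward orientation.
    """
    scan = _ScanParams(params)
    k = params.effective_seed_k
    best = None
    for orientation, arr in ((FORWARD, etc[0]), (REVCOMP, etc[1])):
        offsets = None if exhaustive else seed_diagonals(emk, arr, k)
        hit = _scan_offsets(emk, arr, scan, offsets, rank="identity")
        if hit is None:
            continue
        _, ov, m = hit
        key = (m / ov, ov, orientation == FORWARD)
        if best is None or key > best[0]:
            best = (key, m / ov, ov, orientation)
    return best


def anchor_align(tc_seq: str, marker_seq: str, params: AnchorParams | None = None,
                 *, tc_id: str = "TC", marker_id: str = "marker",
                 chromosome: int = 0, position_cM: float = 0.0,
                 exhaustive: bool = True) -> AnchorHit | None:
    """Align one TC against one marker sequence; hit iff both thresholds pass."""
    params = params or AnchorParams()
    if len(marker_seq) < params.min_overlap_bp:
        return None
    etc = (encode(tc_seq), encode(revcomp(tc_seq)))
    best = _best_placement(etc, encode(marker_seq), params, exhaustive=exhaustive)
    if best is None:
        return None
    _, identity, ov, orientation = best
    return AnchorHit(tc_id, marker_id, chromosome, position_cM, identity, ov, orientation)


def map_transcripts(tcs: dict[str, str], markers: pd.DataFrame,
                    params: AnchorParams | None = None) -> pd.DataFrame:
    """All threshold-passing (TC, marker locus) pairs as a tidy hits table.

    ``markers`` needs columns ``marker_id, chromosome, position_cM, sequence``
    with unique marker ids.  Every passing locus is recorded; a TC is "mapped"
    when it has at least one hit.  Rows are ordered by tc_id (input order)
    then marker_id.
    """
    params = params or AnchorParams()
    if markers["marker_id"].duplicated().any():
        dupes = markers.loc[markers["marker_id"].duplicated(), "marker_id"].tolist()
        raise ValueError(f"duplicate marker ids: {dupes}")
    k = params.effective_seed_k
    usable = markers[markers["sequence"].str.len() >= params.min_overlap_bp]
    if len(usable) < len(markers):
        logger.info("%d markers shorter than %d bp skipped",
                    len(markers) - len(usable), params.min_overlap_bp)
    # Index marker k-mers (with positions) once; per TC only the seeded
    # diagonals of markers sharing a k-mer are scored.
    index: dict[bytes, list[tuple[int, int]]] = {}
    marker_rows = list(usable.itertuples(index=False))
    encoded_markers = []
    for mi, row in enumerate(marker_rows):
        emk = encode(row.sequence)
        encoded_markers.append(emk)
        buf = emk.tobytes()
        for j in range(len(buf) - k + 1):
            index.setdefault(buf[j : j + k], []).append((mi, j))
    scan = _ScanParams(params)
    rows = []
    for tc_id, seq in tcs.items():
        etc = (encode(seq), encode(revcomp(seq)))
        # diagonals[(marker, orientation)] = offsets of the oriented TC
        # relative to the marker sequence
        diagonals: dict[tuple[int, str], set[int]] = {}
        for orientation, arr in ((FORWARD, etc[0]), (REVCOMP, etc[1])):
            buf = arr.tobytes()
            for q in range(len(buf) - k + 1):
                for mi, p in index.get(buf[q : q + k], ()):
                    diagonals.setdefault((mi, orientation), set()).add(p - q)
        for mi in sorted({m for m, _ in diagonals},
                         key=lambda m: marker_rows[m].marker_id):
            best = None
            for orientation, arr in ((FORWARD, etc[0]), (REVCOMP, etc[1])):
                offsets = sorted(diagonals.get((mi, orientation), ()))
                if not offsets:
                    continue
                hit = _scan_offsets(encoded_markers[mi], arr, scan, offsets,
                                    rank="identity")
                if hit is None:
                    continue
                _, ov, m = hit
                key = (m / ov, ov, orientation == FORWARD)
                if best is None or key > best[0]:
                    best = (key, m / ov, ov, orientation)
            if best is None:
                continue
            row = marker_rows[mi]
            _, identity, ov, orientation = best
            rows.append((tc_id, row.marker_id, int(row.chromosome),
                         float(row.position_cM), identity, ov, orientation))
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def mapping_summary(hits: pd.DataFrame) -> MappingStats:
    """Set-cardinality summary of a hits table."""
    if hits.empty:
        return MappingStats(0, 0, 0, 0)
    per_tc = hits.groupby("tc_id")["marker_id"].nunique()
    per_locus = hits.groupby("marker_id")["tc_id"].nunique()
    return MappingStats(
        n_tc_mapped=int(per_tc.size),
        n_loci_hit=int(per_locus.size),
        n_loci_multi_tc=int((per_locus >= 2).sum()),
        n_tc_multi_locus=int((per_tc >= 2).sum()),
    )


__all__ = ["AnchorParams", "AnchorHit", "MappingStats", "HIT_COLUMNS",
           "anchor_align", "map_transcripts", "mapping_summary"]
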