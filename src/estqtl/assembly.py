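"""Greedy overlap clustering of ESTs into tentative consensus sequences (TCs).

Expressed sequence tags are single-pass cDNA reads; reads sampled from the
same transcript overlap, and a threshold on gap-free overlap identity (default
90% identity over at least 80 bp) defines which pairs are joined.  Clusters
are the single-linkage components of the resulting overlap graph; each cluster
yields one tentative consensus sequence, either a singleton (one member read)
or an assembly (two or more reads laid out by their pairwise offsets with a
per-column majority base call).

The alignment model is deliberately gap-free: placements are scored over every
relative offset of the two reads, in both orientations, and the best placement
is the one maximising the number of matching bases among placements that meet
both thresholds.  ``N`` never counts as a match.  An exact-seed diagonal
filter accelerates the scan without changing its result (see
:func:`estqtl._seqops.exact_seed_length`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seqops import (
    SequenceError,
    count_matches,
    decode,
    encode,
    exact_seed_length,
    revcomp,
    seed_diagonals,
)

FORWARD = "forward"
REVCOMP = "reverse-complement"

_N = 4


@dataclass(frozen=True)
class AssemblyParams:
    """Pairwise overlap acceptance thresholds.

    min_identity
        Minimum fraction of matching bases over the overlapped span.
    min_overlap_bp
        Minimum length of the overlapped span in base pairs.
    seed_k
        Requested exact-seed size for the diagonal prefilter; clamped at run
        time to the largest size that provably loses no qualifying placement.
    """

    min_identity: float = 0.90
    min_overlap_bp: int = 80
    seed_k: int = 16

    def __post_init__(self) -> None:
        if not (0 < self.min_identity <= 1):
            raise ValueError("min_identity must be in (0, 1]")
        if self.min_overlap_bp < 1:
            raise ValueError("min_overlap_bp must be >= 1")
        if self.seed_k < 1:
            raise ValueError("seed_k must be >= 1")

    @property
    def effective_seed_k(self) -> int:
        return min(self.seed_k, exact_seed_length(self.min_identity, self.min_overlap_bp))


@dataclass(frozen=True)
class OverlapResult:
    """Best gap-free placement of read b against read a.

    ``offset`` is the position of b's start relative to a's start (negative
    when b hangs off a's left end); ``orientation`` says whether b was
    reverse-complemented before placement.
    """

    offset: int
    overlap_len: int
    matches: int
    orientation: str

    @property
    def identity(self) -> float:
        return self.matches / self.overlap_len


@dataclass
class TentativeConsensus:
    tc_id: str
    consensus: str
    member_read_ids: list[str]

    @property
    def is_singleton(self) -> bool:
        return len(self.member_read_ids) == 1


@dataclass
class AssemblyStats:
    n_tc: int = 0
    n_singletons: int = 0
    n_assemblies: int = 0


@dataclass
class AssemblyResult:
    tcs: list[TentativeConsensus]
    stats: AssemblyStats
    layout_warnings: list[str] = field(default_factory=list)

    def membership(self) -> list[tuple[str, str]]:
        return [(tc.tc_id, rid) for tc in self.tcs for rid in tc.member_read_ids]


def _scan_offsets(ea, eb, params, offsets=None, rank: str = "matches"):
    """Best threshold-passing placement ``(offset, overlap_len, matches)`` or None.

    When ``offsets`` is given only those diagonals are scored; otherwise every
    placement with at least ``min_overlap_bp`` overlapped bases is scored.
    ``rank`` chooses the ordering among qualifying placements: ``"matches"``
    (most matching bases, ties by higher identity) for read-overlap detection,
    ``"identity"`` (highest identity, ties by longer overlap) for marker
    anchoring.  Final ties go to the smaller offset.
    """
    la, lb = len(ea), len(eb)
    min_ov = params.min_overlap_bp
    if offsets is None:
        offsets = range(min_ov - lb, la - min_ov + 1)
    best = None
    for off in offsets:
        a_lo = max(0, off)
        a_hi = min(la, off + lb)
        ov = a_hi - a_lo
        if ov < min_ov:
            continue
        m = count_matches(ea[a_lo:a_hi], eb[a_lo - off : a_hi - off])
        # ratio-form comparison: m/ov and a decimal threshold like 0.9 round
        # to the same double when the identity is exactly at threshold
        if m / ov < params.min_identity:
            continue
        key = (m, m / ov, -off) if rank == "matches" else (m / ov, ov, -off)
        if best is None or key > best[0]:
            best = (key, off, ov, m)
    if best is None:
        return None
    return best[1], best[2], best[3]


def overlap_align(a: str, b: str, params: AssemblyParams | None = None, *,
                  exhaustive: bool = True) -> OverlapResult | None:
    """Best threshold-passing gap-free placement of b on a, either orientation.

    Returns ``None`` when no placement reaches both ``min_overlap_bp`` and
    ``min_identity``.  With ``exhaustive=False`` the offset scan is restricted
    to exact-seed diagonals, which gives the same answer for any pair that has
    a qualifying placement (the seed size is clamped to a lossless value).
    """
    params = params or AssemblyParams()
    ea, eb = encode(a), encode(b)
    k = params.effective_seed_k
    best: tuple | None = None
    for orientation, seq_b in ((FORWARD, eb), (REVCOMP, encode(revcomp(b)))):
        offsets = None if exhaustive else seed_diagonals(ea, seq_b, k)
        hit = _scan_offsets(ea, seq_b, params, offsets)
        if hit is None:
            continue
        off, ov, m = hit
        key = (m, m / ov, orientation == FORWARD, -off)
        if best is None or key > best[0]:
            best = (key, OverlapResult(off, ov, m, orientation))
    return None if best is None else best[1]


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _candidate_diagonals(encoded: list[np.ndarray], rc_encoded: list[np.ndarray],
                         k: int) -> dict[tuple[int, int, str], set[int]]:
    """Seeded diagonals for every read pair sharing an exact k-mer.

    Keys are ``(i, j, orientation)`` with ``i < j``; values are candidate
    offsets of read j (in that orientation) relative to read i's forward
    sequence.  One global k-mer index of the forward sequences is probed with
    both orientations of every higher-index read, so each qualifying
    placement (which necessarily contains an exact run of length >= k)
    contributes its diagonal.
    """
    index: dict[bytes, list[tuple[int, int]]] = {}
    for i, ea in enumerate(encoded):
        buf = ea.tobytes()
        for pos in range(len(buf) - k + 1):
            index.setdefault(buf[pos : pos + k], []).append((i, pos))
    diags: dict[tuple[int, int, str], set[int]] = {}
    for j in range(len(encoded)):
        for orientation, arr in ((FORWARD, encoded[j]), (REVCOMP, rc_encoded[j])):
            buf = arr.tobytes()
            for q in range(len(buf) - k + 1):
                for i, p in index.get(buf[q : q + k], ()):
                    if i < j:
                        diags.setdefault((i, j, orientation), set()).add(p - q)
    return diags


def cluster_ests(reads: dict[str, str], params: AssemblyParams | None = None
                 ) -> list[list[str]]:
    """Single-linkage partition of reads under the pairwise overlap threshold.

    Returns clusters as lists of read ids; clusters are ordered by first
    appearance of a member in the input, members in input order.  The
    partition covers every read exactly once.
    """
    params = params or AssemblyParams()
    ids = list(reads)
    if not ids:
        return []
    encoded = [encode(reads[r]) for r in ids]
    rc_encoded = [encode(revcomp(reads[r])) for r in ids]
    k = params.effective_seed_k
    diags = _candidate_diagonals(encoded, rc_encoded, k)
    pairs = sorted({(i, j) for (i, j, _) in diags})
    uf = _UnionFind(len(ids))
    for i, j in pairs:
        if uf.find(i) == uf.find(j):
            continue  # single linkage: an extra edge cannot change the partition
        for orientation, eb in ((FORWARD, encoded[j]), (REVCOMP, rc_encoded[j])):
            offsets = sorted(diags.get((i, j, orientation), ()))
            if offsets and _scan_offsets(encoded[i], eb, params, offsets) is not None:
                uf.union(i, j)
                break
    groups: dict[int, list[str]] = {}
    first_seen: dict[int, int] = {}
    for idx, rid in enumerate(ids):
        root = uf.find(idx)
        groups.setdefault(root, []).append(rid)
        first_seen.setdefault(root, idx)
    order = sorted(groups, key=lambda root: first_seen[root])
    return [groups[root] for root in order]


def call_consensus(cluster: list[str], reads: dict[str, str],
                   params: AssemblyParams | None = None,
                   cycle_tolerance_bp: int = 5) -> tuple[str, list[str]]:
    """Majority-base consensus for one cluster; returns (consensus, warnings).

    Reads are laid out by propagating accepted pairwise offsets breadth-first
    from the longest member (ties broken by read id), orientation-normalised
    to that anchor.  Non-tree overlaps whose implied offset disagrees with the
    propagated layout by more than ``cycle_tolerance_bp`` are reported as
    layout warnings and the spanning-tree offsets are kept.  Column ties are
    broken by the lexicographically smaller base; N is ignored unless a column
    holds nothing else.
    """
    params = params or AssemblyParams()
    if len(cluster) == 1:
        return reads[cluster[0]], []
    anchor = max(cluster, key=lambda r: (len(reads[r]), r))
    placed: dict[str, tuple[int, str]] = {anchor: (0, FORWARD)}
    oriented: dict[str, str] = {anchor: reads[anchor]}
    warnings: list[str] = []
    frontier = [anchor]
    pending = [r for r in cluster if r != anchor]
    while frontier:
        nxt: list[str] = []
        for ref in frontier:
            for rid in list(pending):
                res = overlap_align(oriented[ref], reads[rid], params, exhaustive=False)
                if res is None:
                    continue
                seq = reads[rid] if res.orientation == FORWARD else revcomp(reads[rid])
                placed[rid] = (placed[ref][0] + res.offset, FORWARD)
                oriented[rid] = seq
                pending.remove(rid)
                nxt.append(rid)
        frontier = nxt
    # Reads unreachable through accepted overlaps from the anchor (possible
    # only when linkage went through a member placed later) get one more pass
    # against every placed read.
    for rid in list(pending):
        for ref in sorted(placed):
            res = overlap_align(oriented[ref], reads[rid], params, exhaustive=False)
            if res is not None:
                seq = reads[rid] if res.orientation == FORWARD else revcomp(reads[rid])
                placed[rid] = (placed[ref][0] + res.offset, FORWARD)
                oriented[rid] = seq
                pending.remove(rid)
                break
    for rid in pending:  # pragma: no cover - defensive, linkage guarantees reachability
        placed[rid] = (0, FORWARD)
        oriented[rid] = reads[rid]
        warnings.append(f"read {rid} could not be placed; anchored at offset 0")
    # Cycle consistency check on non-tree pairs.
    members = sorted(placed)
    for x in range(len(members)):
        for y in range(x + 1, len(members)):
            rx, ry = members[x], members[y]
            res = overlap_align(oriented[rx], oriented[ry], params, exhaustive=False)
            if res is not None and res.orientation == FORWARD:
                implied = placed[rx][0] + res.offset
                if abs(implied - placed[ry][0]) > cycle_tolerance_bp:
                    warnings.append(
                        f"overlap {rx}/{ry} implies offset {implied}, "
                        f"layout has {placed[ry][0]}; keeping spanning-tree layout"
                    )
    lo = min(off for off, _ in placed.values())
    hi = max(placed[r][0] + len(oriented[r]) for r in placed)
    counts = np.zeros((hi - lo, 5), dtype=np.int32)
    for rid in members:
        off = placed[rid][0] - lo
        arr = encode(oriented[rid])
        counts[off : off + len(arr)][np.arange(len(arr)), arr] += 1
    acgt = counts[:, :4]
    covered = acgt.sum(axis=1) > 0
    best = np.argmin(-acgt, axis=1)  # argmin of negated counts -> first max, A<C<G<T tie-break
    cols = np.where(covered, best, _N)
    return decode(cols.astype(np.uint8)), warnings


def assemble(reads: dict[str, str], params: AssemblyParams | None = None
             ) -> AssemblyResult:
    """Cluster reads and call one tentative consensus per cluster.

    TC ids are ``TC_1`` ... ``TC_n`` in cluster order; ``n_tc`` always equals
    ``n_singletons + n_assemblies``.
    """
    params = params or AssemblyParams()
    clusters = cluster_ests(reads, params)
    tcs: list[TentativeConsensus] = []
    warnings: list[str] = []
    for i, cluster in enumerate(clusters, start=1):
        consensus, warns = call_consensus(cluster, reads, params)
        warnings.extend(warns)
        tcs.append(TentativeConsensus(f"TC_{i}", consensus, list(cluster)))
    n_single = sum(tc.is_singleton for tc in tcs)
    stats = AssemblyStats(n_tc=len(tcs), n_singletons=n_single,
                          n_assemblies=len(tcs) - n_single)
    return AssemblyResult(tcs, stats, warnings)


__all__ = [
    "AssemblyParams",
    "OverlapResult",
    "TentativeConsensus",
    "AssemblyStats",
    "AssemblyResult",
    "overlap_align",
    "cluster_ests",
    "call_consensus",
    "assemble",
    "SequenceError",
]
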