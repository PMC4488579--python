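"""Low-level nucleotide sequence helpers shared by the assembler and anchorer.

Sequences cross the public API as plain ``str`` over the alphabet
``{A, C, G, T, N}``; internally they are encoded as small ``uint8`` arrays so
that gap-free placements can be scored with vectorised comparisons.
"""

from __future__ import annotations

import numpy as np

# A=0 C=1 G=2 T=3 N=4 -- N never counts as a match.
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGTN"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lower case
_N = 4

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

_RC_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class SequenceError(ValueError):
    """Raised for empty sequences or characters outside {A,C,G,T,N}."""


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as a uint8 array, validating the alphabet."""
    if not seq:
        raise SequenceError("empty sequence")
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        bad = seq[int(np.argmax(arr == 255))]
        raise SequenceError(f"invalid nucleotide character {bad!r}")
    return arr


def decode(arr: np.ndarray) -> str:
    return _DECODE[arr].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    """Reverse complement; N maps to N."""
    return seq.translate(_RC_TABLE)[::-1]


def count_matches(ea: np.ndarray, eb: np.ndarray) -> int:
    """Matching positions between equal-length encoded arrays; N never matches."""
    return int(np.count_nonzero((ea == eb) & (ea != _N)))


def exact_seed_length(min_identity: float, min_overlap: int) -> int:
    """Longest k guaranteeing an exact shared k-mer in any qualifying overlap.

    A gap-free overlap of length L at identity >= min_identity has at most
    m = floor(L * (1 - min_identity)) mismatches, hence by pigeonhole an exact
    run of at least ceil((L - m) / (m + 1)) bases on its diagonal.  The
    minimum of that guarantee over all admissible L is the largest seed size
    for which diagonal seeding loses no qualifying placement.
    """
    if not (0 < min_identity <= 1):
        raise ValueError("min_identity must be in (0, 1]")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if min_identity == 1.0:
        return min_overlap

    def min_matches(length: int) -> int:
        # smallest q with q/length >= min_identity under the scanner's own
        # floating-point comparison, so the bound matches acceptance exactly
        q = int(np.ceil(min_identity * length))
        while q > 0 and (q - 1) / length >= min_identity:
            q -= 1
        while q / length < min_identity:
            q += 1
        return q

    best = min_overlap
    # The guarantee approaches id/(1-id) from above as L grows; scanning a
    # few multiples of the minimum overlap plus that asymptote covers the min.
    for length in range(min_overlap, max(min_overlap * 20, min_overlap + 200)):
        q = min_matches(length)
        m = length - q
        best = min(best, -(-q // (m + 1)))  # ceil(q / (m+1))
    best = min(best, int(np.floor(min_identity / (1.0 - min_identity))))
    return max(best, 1)


def seed_diagonals(ea: np.ndarray, eb: np.ndarray, k: int) -> list[int]:
    """Offsets (start of b relative to start of a) carrying a shared exact k-mer.

    Offsets are returned sorted and deduplicated.  Any gap-free placement that
    contains an exact match run of length >= k appears in this list, so
    restricting the offset scan to these diagonals is lossless whenever
    k <= exact_seed_length(...) for the acceptance thresholds in force.
    """
    la, lb = len(ea), len(eb)
    if k > la or k > lb:
        return []
    index: dict[bytes, list[int]] = {}
    abuf = ea.tobytes()
    for i in range(la - k + 1):
        index.setdefault(abuf[i : i + k], []).append(i)
    bbuf = eb.tobytes()
    diagonals: set[int] = set()
    for j in range(lb - k + 1):
        for i in index.get(bbuf[j : j + k], ()):
            diagonals.add(i - j)
    return sorted(diagonals)
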