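"""Shared fixtures and independent brute-force oracles.

The oracles here are deliberately written in plain Python over strings —
no numpy, no shared helpers with the package — so that agreement tests pit
two genuinely different code paths against each other.
"""

from __future__ import annotations

import random

import pandas as pd
import pytest

from estqtl.pipeline import (load_candidate_fixture_df, load_contingency_fixture,
                             load_region_fixture, load_synteny_fixture,
                             region_fixture_as_qtls)

_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_RC[b] for b in reversed(seq))


def random_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def mutate(seq: str, rng: random.Random, n_sub: int) -> str:
    """Apply exactly n_sub substitutions at distinct positions."""
    out = list(seq)
    for pos in rng.sample(range(len(seq)), n_sub):
        out[pos] = rng.choice([b for b in "ACGT" if b != out[pos]])
    return "".join(out)


def oracle_best_overlap(a: str, b: str, min_identity: float, min_overlap: int,
                        rank: str = "matches"):
    """Exhaustive all-offsets/both-orientations scan, pure Python.

    Returns ``(matches, overlap, identity, orientation)`` of the best
    threshold-passing placement or ``None``.  ``rank='matches'`` prefers the
    most matching bases (the read-overlap rule); ``rank='identity'`` prefers
    the highest identity then the longest overlap (the anchoring rule).
    """
    best = None
    for orientation in ("forward", "reverse-complement"):
        bb = b if orientation == "forward" else rc(b)
        for off in range(-len(bb) + 1, len(a)):
            lo, hi = max(0, off), min(len(a), off + len(bb))
            ov = hi - lo
            if ov < min_overlap:
                continue
            m = sum(1 for i in range(lo, hi)
                    if a[i] == bb[i - off] and a[i] != "N")
            if m / ov < min_identity:
                continue
            key = (m, m / ov) if rank == "matches" else (m / ov, ov)
            if best is None or key > best[0]:
                best = (key, m, ov, m / ov, orientation)
    return None if best is None else best[1:]


def oracle_partition(reads: dict[str, str], min_identity: float,
                     min_overlap: int) -> set[frozenset]:
    """Single-linkage components from the all-pairs brute-force oracle."""
    ids = list(reads)
    parent = {r: r for r in ids}

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for i, ri in enumerate(ids):
        for rj in ids[i + 1:]:
            if oracle_best_overlap(reads[ri], reads[rj], min_identity,
                                   min_overlap) is not None:
                parent[find(ri)] = find(rj)
    groups: dict[str, set] = {}
    for r in ids:
        groups.setdefault(find(r), set()).add(r)
    return {frozenset(g) for g in groups.values()}


@pytest.fixture(scope="session")
def region_fixture() -> pd.DataFrame:
    return load_region_fixture()


@pytest.fixture(scope="session")
def region_qtls(region_fixture) -> pd.DataFrame:
    return region_fixture_as_qtls(region_fixture)


@pytest.fixture(scope="session")
def contingency_fixture():
    return load_contingency_fixture()


@pytest.fixture(scope="session")
def candidate_fixture() -> pd.DataFrame:
    return load_candidate_fixture_df()


@pytest.fixture(scope="session")
def synteny_fixture() -> pd.DataFrame:
    return load_synteny_fixture()
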