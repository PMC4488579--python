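"""Overlap alignment, single-linkage clustering and consensus calling."""

from __future__ import annotations

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from estqtl.assembly import (AssemblyParams, SequenceError, assemble,
                             call_consensus, cluster_ests, overlap_align)
from estqtl._seqops import exact_seed_length, revcomp

from conftest import mutate, oracle_best_overlap, oracle_partition, random_seq


class TestOverlapAlign:
    def test_identical_reads_full_overlap(self):
        rng = random.Random(0)
        a = random_seq(rng, 120)
        res = overlap_align(a, a)
        assert (res.offset, res.overlap_len, res.identity) == (0, 120, 1.0)
        assert res.orientation == "forward"

    def test_single_substitution_accepted(self):
        rng = random.Random(1)
        a = random_seq(rng, 100)
        b = mutate(a, rng, 1)
        res = overlap_align(a, b)
        assert res is not None
        assert res.identity == pytest.approx(0.99)

    def test_overlap_below_minimum_rejected(self):
        # 79 bp reads cannot reach the 80 bp minimum overlap
        rng = random.Random(2)
        a = random_seq(rng, 79)
        assert overlap_align(a, a) is None

    def test_exact_identity_threshold_accepted(self):
        # exactly 90% identity over exactly the minimum overlap must pass
        rng = random.Random(3)
        a = random_seq(rng, 80)
        b = mutate(a, rng, 8)
        res = overlap_align(a, b)
        assert res is not None and res.identity >= 0.90

    def test_n_never_matches(self):
        a = "ACGT" * 30
        b = "N" * 120
        assert overlap_align(a, b) is None

    def test_empty_sequence_is_an_error(self):
        with pytest.raises(SequenceError):
            overlap_align("", "ACGT")

    @pytest.mark.parametrize("seed", range(4))
    def test_agrees_with_bruteforce_oracle(self, seed):
        """Seeded scan equals the exhaustive pure-Python oracle on 150 bp pairs."""
        rng = random.Random(100 + seed)
        params = AssemblyParams()
        for trial in range(125):
            a = random_seq(rng, 150)
            kind = trial % 5
            if kind == 0:          # unrelated
                b = random_seq(rng, 150)
            else:                  # shifted, mutated, possibly flipped copy
                shift = rng.randrange(0, 60)
                b = a[shift:] + random_seq(rng, shift)
                b = mutate(b, rng, rng.randrange(0, 18))
                if kind == 3:
                    b = revcomp(b)
            mine = overlap_align(a, b, params)
            ref = oracle_best_overlap(a, b, 0.90, 80)
            if ref is None:
                assert mine is None
            else:
                m, ov, ident, _ = ref
                assert mine is not None
                assert (mine.matches, mine.overlap_len) == (m, ov)
                assert mine.identity == pytest.approx(ident)

    def test_symmetry_of_identity_and_overlap(self):
        rng = random.Random(7)
        for _ in range(40):
            a = random_seq(rng, 140)
            shift = rng.randrange(0, 40)
            b = mutate(a[shift:] + random_seq(rng, shift), rng, rng.randrange(0, 10))
            ab = overlap_align(a, b)
            ba = overlap_align(b, a)
            assert (ab is None) == (ba is None)
            if ab is not None:
                assert ab.overlap_len == ba.overlap_len
                assert ab.matches == ba.matches


class TestClustering:
    def test_identical_reads_form_one_cluster(self):
        rng = random.Random(11)
        seq = random_seq(rng, 120)
        clusters = cluster_ests({f"r{i}": seq for i in range(4)})
        assert [sorted(c) for c in clusters] == [["r0", "r1", "r2", "r3"]]

    def test_unrelated_reads_stay_singletons(self):
        rng = random.Random(12)
        reads = {f"r{i}": random_seq(rng, 100) for i in range(5)}
        clusters = cluster_ests(reads)
        assert sorted(len(c) for c in clusters) == [1] * 5

    def test_single_linkage_chains_transitively(self):
        # a-b and b-c overlap above threshold, a-c overlap only 10 bp
        rng = random.Random(13)
        b = random_seq(rng, 200)
        a = b[:110]     # left 110 bp of b
        c = b[100:]     # right 100 bp of b
        reads = {"a": a, "b": b, "c": c}
        assert oracle_best_overlap(a, c, 0.90, 80) is None
        clusters = cluster_ests(reads)
        assert [sorted(cl) for cl in clusters] == [["a", "b", "c"]]

    def test_orientation_invariance_of_partition(self):
        rng = random.Random(14)
        template = random_seq(rng, 400)
        reads = {}
        for i in range(8):
            start = rng.randrange(0, 200)
            frag = template[start : start + 180]
            reads[f"r{i}"] = frag if i % 2 else revcomp(frag)
        flipped = {rid: revcomp(seq) for rid, seq in reads.items()}
        part1 = {frozenset(c) for c in cluster_ests(reads)}
        part2 = {frozenset(c) for c in cluster_ests(flipped)}
        assert part1 == part2

    @pytest.mark.parametrize("seed", range(3))
    def test_partition_equals_bruteforce_on_tiny_instances(self, seed):
        """<=12 reads of <=60 bp: clustering equals all-pairs brute force."""
        rng = random.Random(60 + seed)
        params = AssemblyParams(min_identity=0.90, min_overlap_bp=20)
        templates = [random_seq(rng, 90) for _ in range(3)]
        reads = {}
        for i in range(12):
            t = rng.choice(templates)
            start = rng.randrange(0, 40)
            frag = t[start : start + rng.randrange(30, 61)]
            frag = mutate(frag, rng, rng.randrange(0, 3))
            if rng.random() < 0.5:
                frag = revcomp(frag)
            reads[f"r{i}"] = frag
        expected = oracle_partition(reads, 0.90, 20)
        got = {frozenset(c) for c in cluster_ests(reads, params)}
        assert got == expected

    def test_partition_covers_every_read_once(self):
        rng = random.Random(15)
        template = random_seq(rng, 500)
        reads = {f"r{i}": template[s : s + 150]
                 for i, s in enumerate(rng.sample(range(0, 350), 10))}
        clusters = cluster_ests(reads)
        members = [r for c in clusters for r in c]
        assert sorted(members) == sorted(reads)


class TestConsensus:
    def test_two_identical_reads(self):
        rng = random.Random(20)
        seq = random_seq(rng, 150)
        consensus, warns = call_consensus(["a", "b"], {"a": seq, "b": seq})
        assert consensus == seq and warns == []

    def test_majority_base_wins(self):
        rng = random.Random(21)
        base = random_seq(rng, 120)
        pos = 60
        variant = base[:pos] + ("G" if base[pos] != "G" else "T") + base[pos + 1:]
        reads = {"a": base, "b": base, "c": variant}
        consensus, _ = call_consensus(["a", "b", "c"], reads)
        assert consensus == base

    def test_column_tie_breaks_lexicographically(self):
        rng = random.Random(22)
        base = random_seq(rng, 120)
        pos = 50
        v1 = base[:pos] + "A" + base[pos + 1:]
        v2 = base[:pos] + "G" + base[pos + 1:]
        consensus, _ = call_consensus(["a", "b"], {"a": v1, "b": v2})
        assert consensus[pos] == "A"

    def test_reverse_complement_member_is_normalised(self):
        # consensus is reported in the anchor read's orientation
        rng = random.Random(23)
        seq = random_seq(rng, 150)
        consensus, _ = call_consensus(["a", "b"], {"a": seq, "b": revcomp(seq)})
        assert consensus in (seq, revcomp(seq))


class TestAssemble:
    def _tiled_reads(self, rng, n_genes):
        """Three error-free reads per gene with 80+ bp mutual overlaps."""
        reads = {}
        for g in range(n_genes):
            template = random_seq(rng, 300)
            for j, (lo, hi) in enumerate([(0, 160), (80, 240), (140, 300)]):
                reads[f"g{g}_r{j}"] = template[lo:hi]
        return reads

    def test_recovers_one_tc_per_source_gene(self):
        rng = random.Random(30)
        n_genes = 50
        result = assemble(self._tiled_reads(rng, n_genes))
        assert result.stats.n_tc == n_genes
        assert result.stats.n_assemblies == n_genes
        # each TC's members come from a single gene
        for tc in result.tcs:
            genes = {rid.split("_")[0] for rid in tc.member_read_ids}
            assert len(genes) == 1

    def test_stats_identity_and_partition(self):
        rng = random.Random(31)
        reads = self._tiled_reads(rng, 10)
        reads.update({f"lone{i}": random_seq(rng, 120) for i in range(5)})
        result = assemble(reads)
        assert result.stats.n_tc == result.stats.n_singletons + result.stats.n_assemblies
        members = [r for tc in result.tcs for r in tc.member_read_ids]
        assert sorted(members) == sorted(reads)
        for tc in result.tcs:
            assert tc.is_singleton == (len(tc.member_read_ids) == 1)

    def test_empty_input(self):
        result = assemble({})
        assert result.tcs == [] and result.stats.n_tc == 0


@settings(max_examples=30, deadline=None)
@given(st.integers(1, 10).flatmap(
    lambda n: st.lists(st.sampled_from("ACGT"), min_size=n * 10,
                       max_size=n * 10).map("".join)))
def test_revcomp_is_an_involution(seq):
    assert revcomp(revcomp(seq)) == seq


@pytest.mark.parametrize("identity,overlap,expected_max", [
    (0.90, 80, 8), (0.90, 100, 9), (1.0, 40, 40)])
def test_exact_seed_bound(identity, overlap, expected_max):
    """Pigeonhole seed bound: any qualifying overlap has an exact run this long."""
    assert exact_seed_length(identity, overlap) == expected_max
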