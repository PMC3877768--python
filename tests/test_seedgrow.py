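import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirseed.errors import ReferenceError_
from mirseed.hybridscan import ANTI_MIR21
from mirseed.seedgrow import (
    MatchRecord,
    build_index,
    enumerate_seeds,
    export_stack,
    match_library,
    match_read,
    reverse_complement,
)
from mirseed.seqio import ReferenceSmallRNA


def brute_force_matches(read, refs, k=16):
    """Independent oracle: extend every (read offset, ref offset) base pair
    maximally and keep distinct runs of length >= k."""
    found = set()
    for ref in refs:
        rs = ref.sequence
        for i in range(len(read)):
            for j in range(len(rs)):
                if read[i] != rs[j] or read[i] == "N":
                    continue
                a, b = i, j
                while a > 0 and b > 0 and read[a - 1] == rs[b - 1] and read[a - 1] != "N":
                    a -= 1
                    b -= 1
                x, y = i + 1, j + 1
                while x < len(read) and y < len(rs) and read[x] == rs[y] and read[x] != "N":
                    x += 1
                    y += 1
                if x - a >= k:
                    found.add((ref.ref_id, b + 1, y, read[:a], read[x:]))
    return found


def as_tuples(records):
    return {(r.ref_id, r.ref_start, r.ref_end, r.flank5, r.flank3) for r in records}


class TestEnumerateSeeds:
    def test_23nt_reference_has_eight_16nt_seeds(self, ref23):
        seeds = enumerate_seeds(ref23, 16)
        assert len(seeds) == 8
        assert [off for off, _ in seeds] == list(range(8))
        assert all(len(kmer) == 16 for _, kmer in seeds)

    def test_reference_equal_to_seed_length(self):
        ref = ReferenceSmallRNA("r16", "ACGTACGTACGTACGT")
        assert enumerate_seeds(ref, 16) == [(0, "ACGTACGTACGTACGT")]

    def test_printed_antagomir_has_ten_seeds(self):
        anti = ReferenceSmallRNA("anti-miR21", ANTI_MIR21, "antagomir")
        seeds = enumerate_seeds(anti, 16)
        # brute-force enumeration of all 16-mers of the 25-nt sequence
        brute = [anti.sequence[i : i + 16] for i in range(len(anti.sequence) - 15)]
        assert [kmer for _, kmer in seeds] == brute
        assert len(seeds) == 10

    def test_too_short_reference_names_ref(self):
        with pytest.raises(ReferenceError_, match="shorty"):
            enumerate_seeds(ReferenceSmallRNA("shorty", "ACGTACGT"), 16)


class TestBuildIndex:
    def test_single_reference_seed_count(self, ref23):
        index = build_index([ref23], 16)
        assert sum(len(v) for v in index.entries.values()) == 8

    def test_reverse_complement_indexing(self):
        ref = ReferenceSmallRNA("r16", "ACGTACGTACGTACGA")
        index = build_index([ref], 16, add_reverse_complements=True)
        assert set(index.references) == {"r16", "r16|rc"}
        assert index.references["r16|rc"].sequence == reverse_complement(ref.sequence)

    def test_shared_kmer_maps_to_both_references(self):
        shared = "ACGTTGCAACGTTGCA"
        r1 = ReferenceSmallRNA("r1", shared + "AAAA")
        r2 = ReferenceSmallRNA("r2", "GG" + shared)
        index = build_index([r1, r2], 16)
        assert set(index.lookup(shared)) == {("r1", 0), ("r2", 2)}

    def test_duplicate_ref_id_rejected(self, ref23):
        with pytest.raises(ReferenceError_, match="duplicate"):
            build_index([ref23, ref23], 16)


class TestMatchRead:
    def test_identity_match(self):
        ref = ReferenceSmallRNA("r22", "TAGCTTATCAGACTGATGTTGA")
        index = build_index([ref], 16)
        (rec,) = match_read(ref.sequence, index)
        assert (rec.ref_start, rec.ref_end) == (1, 22)
        assert rec.flank5 == "" and rec.flank3 == ""
        assert rec.matched_length == 22

    def test_mismatching_prefix_becomes_flank5(self):
        ref = ReferenceSmallRNA("r22", "TAGCTTATCAGACTGATGTTGA")
        index = build_index([ref], 16)
        # pick a 2-base prefix disagreeing with reference bases 1 and 2 (T, A)
        read = "CC" + ref.sequence[2:20]
        recs = match_read(read, index)
        assert as_tuples(recs) == brute_force_matches(read, [ref])
        top = recs[0]
        assert (top.ref_start, top.ref_end) == (3, 20)
        assert top.flank5 == "CC" and top.flank3 == ""

    def test_no_shared_kmer_gives_empty_list(self, ref23):
        index = build_index([ref23], 16)
        assert match_read("G" * 20, index) == []

    def test_n_bases_never_match(self):
        ref = ReferenceSmallRNA("r22", "TAGCTTATCAGACTGATGTTGA")
        index = build_index([ref], 16)
        read = ref.sequence[:18] + "N" + ref.sequence[19:]
        recs = match_read(read, index)
        assert recs, "18-nt error-free prefix should still anchor"
        assert all(r.ref_end <= 18 or r.ref_start >= 20 for r in recs)
        assert as_tuples(recs) == brute_force_matches(read, [ref])

    @pytest.mark.parametrize("case", range(4))
    def test_oracle_equivalence_random_pairs(self, case):
        """Seed-and-grow equals brute-force all-anchor extension on random
        (read, reference) pairs: identical, mutated, embedded and shuffled."""
        rng = np.random.default_rng(100 + case)
        n_pairs = 300
        for _ in range(n_pairs):
            L_ref = int(rng.integers(16, 41))
            ref_seq = "".join(rng.choice(list("ACGT"), size=L_ref))
            ref = ReferenceSmallRNA("ref", ref_seq)
            if case == 0:  # identical or sub-slice
                s = int(rng.integers(0, max(L_ref - 16, 0) + 1))
                read = ref_seq[s : s + int(rng.integers(16, L_ref + 1))]
                if len(read) < 16:
                    read = ref_seq
            elif case == 1:  # point-mutated copy
                pos = int(rng.integers(0, L_ref))
                read = ref_seq[:pos] + str(rng.choice(list("ACGT"))) + ref_seq[pos + 1 :]
            elif case == 2:  # embedded with random flanks
                f5 = "".join(rng.choice(list("ACGT"), size=int(rng.integers(0, 5))))
                f3 = "".join(rng.choice(list("ACGT"), size=int(rng.integers(0, 5))))
                read = f5 + ref_seq + f3
            else:  # unrelated random read
                read = "".join(rng.choice(list("ACGT"), size=int(rng.integers(16, 41))))
            index = build_index([ref], 16)
            got = match_read(read, index)
            assert as_tuples(got) == brute_force_matches(read, [ref])
            for rec in got:
                rec.validate(ref)

    def test_maximality(self):
        """No record can be extended one base in either direction."""
        rng = np.random.default_rng(7)
        for _ in range(200):
            ref_seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(20, 41))))
            ref = ReferenceSmallRNA("ref", ref_seq)
            pos = int(rng.integers(0, len(ref_seq)))
            read = ref_seq[:pos] + str(rng.choice(list("ACGT"))) + ref_seq[pos + 1 :]
            index = build_index([ref], 16)
            for rec in match_read(read, index):
                i0 = len(rec.flank5)
                i1 = i0 + rec.matched_length
                if rec.ref_start > 1 and i0 > 0:
                    assert read[i0 - 1] != ref_seq[rec.ref_start - 2]
                if rec.ref_end < len(ref_seq) and i1 < len(read):
                    assert read[i1] != ref_seq[rec.ref_end]

    def test_appending_mismatch_grows_exactly_one_flank(self):
        ref = ReferenceSmallRNA("r22", "TAGCTTATCAGACTGATGTTGA")
        index = build_index([ref], 16)
        (before,) = match_read(ref.sequence, index)
        # reference ends in A; append a disagreeing base
        (after,) = match_read(ref.sequence + "C", index)
        assert (after.ref_start, after.ref_end) == (before.ref_start, before.ref_end)
        assert after.flank5 == before.flank5
        assert after.flank3 == before.flank3 + "C"


class TestMatchLibrary:
    def test_occurrences_carried_through(self, ref23):
        index = build_index([ref23], 16)
        records = match_library([(ref23.sequence, 5)], index)
        assert len(records) == 1 and records[0].occurrences == 5

    def test_all_vs_best_mode_on_shared_kmer(self):
        shared = "ACGTTGCAACGTTGCA"
        r1 = ReferenceSmallRNA("rA", shared + "TT")
        r2 = ReferenceSmallRNA("rB", shared + "GG")
        index = build_index([r1, r2], 16)
        all_recs = match_library([(shared, 1)], index, mode="all")
        best = match_library([(shared, 1)], index, mode="best")
        assert {r.ref_id for r in all_recs} == {"rA", "rB"}
        assert len(best) == 1 and best[0].ref_id == "rA"  # tie broken by ref_id

    def test_empty_library(self, ref23):
        index = build_index([ref23], 16)
        assert match_library([], index) == []


class TestExportStack:
    def test_identity_match_two_equal_rows(self, ref23):
        index = build_index([ref23], 16)
        recs = match_library([(ref23.sequence, 3)], index)
        stack = export_stack(recs, ref23).splitlines()
        assert stack[1] == ref23.sequence
        assert stack[3] == ref23.sequence
        assert len(stack[1]) == len(stack[3])

    def test_flank_lowercase_and_padding(self):
        ref = ReferenceSmallRNA("r22", "TAGCTTATCAGACTGATGTTGA")
        index = build_index([ref], 16)
        read = "CC" + ref.sequence[2:20]
        recs = match_library([(read, 1)], index)
        rec = recs[0]
        assert rec.flank5 == "CC" and rec.ref_start == 3
        rows = export_stack(recs, ref).splitlines()
        # flank overhang equals flank width minus reference offset: 2-2=0 pad
        assert rows[1] == ref.sequence
        assert rows[3].startswith("cc" + ref.sequence[2:20])
        assert len(rows[3]) == len(rows[1])

    def test_overhanging_flank_pads_reference(self):
        ref = ReferenceSmallRNA("r20", "TAGCTTATCAGACTGATGTT")
        index = build_index([ref], 16)
        read = "GGG" + ref.sequence  # 3-base 5' overhang
        recs = match_library([(read, 1)], index)
        rows = export_stack(recs, ref).splitlines()
        assert rows[1] == "..." + ref.sequence
        assert rows[3] == "ggg" + ref.sequence

    def test_empty_records_reference_only(self, ref23):
        rows = export_stack([], ref23).splitlines()
        assert rows == [f">{ref23.ref_id}", ref23.sequence]


class TestReverseComplement:
    @pytest.mark.parametrize("seq, expected", [("ACGT", "ACGT"), ("AAAC", "GTTT"), ("AN", "NT")])
    def test_examples(self, seq, expected):
        assert reverse_complement(seq) == expected

    @given(st.text(alphabet="ACGTN", min_size=1, max_size=60))
    @settings(max_examples=100, deadline=None)
    def test_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq
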