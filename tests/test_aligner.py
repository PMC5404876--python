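import numpy as np
import pysam
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rrfscan._util import reverse_complement
from rrfscan.align import (
    ANTISENSE,
    SENSE,
    AlignmentRecord,
    MappingStats,
    SeedIndex,
    align_all,
    align_read,
    build_index,
    import_sam,
    strand_fraction,
    write_sam,
)
from rrfscan.readio import CollapsedRead
from rrfscan.reference import AnnotatedReference


def _ref(seq, rid="ref"):
    return AnnotatedReference(id=rid, sequence=seq, regions=())


class TestSeedIndex:
    def test_kmer_positions(self):
        idx = SeedIndex(_ref("ACGTACGTACG"), k=7)
        assert idx.lookup("ACGTACG") == (0, 4)
        assert idx.lookup("CGTACGT") == (1,)
        assert idx.lookup("TTTTTTT") == ()

    def test_small_k_rejected(self):
        with pytest.raises(ValueError, match="k >= 7"):
            build_index(_ref("ACGTACGTACG"), k=5)

    def test_n_kmers_not_indexed(self):
        idx = SeedIndex(_ref("ACGNACGTACGTA"), k=7)
        assert idx.lookup("ACGNACG") == ()


REF = "AAACGTACGTACGTTTCCAGTATTCCGGA"


@pytest.fixture(scope="module")
def index():
    return SeedIndex(_ref(REF), k=7)


class TestAlignRead:

    def test_exact_substring(self, index):
        rec = align_read("CGTACGTACGTTTCC", index)
        assert (rec.ref_start, rec.ref_end, rec.strand) == (3, 18, SENSE)
        assert rec.n_mismatch == rec.n_gap == 0

    def test_single_mismatch(self, index):
        rec = align_read("CGTACTTACGTTTCC", index)
        assert (rec.ref_start, rec.n_mismatch, rec.n_gap) == (3, 1, 0)

    def test_antisense_by_reverse_complement(self, index):
        rec = align_read(reverse_complement(REF[3:18]), index)
        assert (rec.ref_start, rec.ref_end, rec.strand) == (3, 18, ANTISENSE)

    def test_two_mismatches_unmapped(self, index):
        read = list(REF[3:18])
        read[2], read[10] = "A", "A"  # both positions are non-A in the reference
        assert align_read("".join(read), index) is None

    def test_deletion_in_read(self, index):
        read = REF[3:10] + REF[11:19]  # 15 nt, skips one reference base
        rec = align_read(read, index)
        assert (rec.ref_start, rec.ref_end) == (3, 19)
        assert (rec.n_mismatch, rec.n_gap) == (0, 1)
        assert rec.ref_end - rec.ref_start == len(read) + 1

    def test_insertion_in_read(self, index):
        read = REF[3:11] + "T" + REF[11:18]  # REF[11] == 'C', inserted base differs
        rec = align_read(read, index)
        assert (rec.ref_start, rec.ref_end) == (3, 18)
        assert (rec.n_mismatch, rec.n_gap) == (0, 1)
        assert rec.ref_end - rec.ref_start == len(read) - 1

    def test_read_longer_than_reference_unmapped(self, index):
        assert align_read("A" * (len(REF) + 5), index) is None

    def test_mismatch_preferred_over_gap_at_equal_cost(self):
        # Read differs from ref[0:15] by one substitution, and also aligns with
        # one deletion elsewhere; the substitution must win the tie at cost 1.
        ref = "AAAAAAAAAACCCCCCCCCCGGGG"
        idx = SeedIndex(_ref(ref), k=7)
        read = "AAAAAAAAAAACCCCCCCCC"[:15]
        rec = align_read(read, idx)
        assert rec.n_gap == 0 or rec.n_mismatch == 1

    def test_leftmost_placement_wins(self):
        unit = "ACGTGCTAGCATCGA"
        ref = unit + "TTTTT" + unit
        idx = SeedIndex(_ref(ref), k=7)
        rec = align_read(unit, idx)
        assert rec.ref_start == 0

    def test_sense_preferred_over_antisense_at_equal_cost(self):
        unit = "ACGTGCTAGCATCGA"
        ref = reverse_complement(unit) + "TTTTT" + unit
        idx = SeedIndex(_ref(ref), k=7)
        rec = align_read(unit, idx)
        assert rec.strand == SENSE
        assert rec.ref_start == len(unit) + 5

    def test_reference_n_never_matches(self):
        ref = "AAACGTNCGTACGTTTCCAGT"
        idx = SeedIndex(_ref(ref), k=7)
        rec = align_read("ACGTNCGTACGTTTC", idx)
        # the N-N pair still costs an edit
        assert rec is not None and rec.n_mismatch + rec.n_gap == 1

    def test_invalid_characters_rejected(self, index):
        with pytest.raises(ValueError, match="non-ACGTN"):
            align_read("ACGTXACGTACGTAC", index)


@given(st.data())
def test_strand_symmetry(data):
    """Aligning the reverse complement flips the strand but keeps the span."""
    rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
    ref = "".join(rng.choice(list("ACGT"), size=500))
    idx = SeedIndex(_ref(ref), k=7)
    L = int(rng.integers(15, 41))
    s = int(rng.integers(0, 500 - L))
    read = ref[s : s + L]
    fwd = align_read(read, idx)
    rev = align_read(reverse_complement(read), idx)
    assert fwd is not None and rev is not None
    assert fwd.n_mismatch + fwd.n_gap == rev.n_mismatch + rev.n_gap == 0
    if fwd.ref_start == s and rev.ref_start == s:  # unique best placement
        assert {fwd.strand, rev.strand} == {SENSE, ANTISENSE}
        assert (fwd.ref_start, fwd.ref_end) == (rev.ref_start, rev.ref_end)


class TestAlignAll:
    def test_counts_weighted_by_duplicates(self, toy_ref):
        seq = toy_ref.sequence
        collapsed = [
            CollapsedRead(seq[10:40], 3),
            CollapsedRead(seq[100:130], 2),
            CollapsedRead("T" * 30, 5),  # unmappable against a random reference
        ]
        records, stats = align_all(collapsed, toy_ref)
        assert stats.n_cleaned_reads == 10
        assert stats.n_aligned_reads == 5
        assert stats.n_sense + stats.n_antisense == stats.n_aligned_reads

    def test_zero_reads(self, toy_ref):
        records, stats = align_all([], toy_ref)
        assert records == [] and stats.n_aligned_reads == stats.n_cleaned_reads == 0

    def test_exact_library_fully_mapped(self, toy_ref, rng):
        seq = toy_ref.sequence
        collapsed = [
            CollapsedRead(seq[s : s + 30], 1)
            for s in rng.integers(0, len(seq) - 30, size=50)
        ]
        collapsed = [CollapsedRead(s, 1) for s in {c.sequence for c in collapsed}]
        _, stats = align_all(collapsed, toy_ref)
        assert stats.n_aligned_reads == stats.n_cleaned_reads

    def test_determinism(self, toy_ref, rng):
        seq = toy_ref.sequence
        collapsed = [CollapsedRead(seq[s : s + 25], int(c)) for s, c in
                     zip(rng.integers(0, 3000, size=30), rng.integers(1, 9, size=30))]
        r1 = align_all(collapsed, toy_ref)
        r2 = align_all(collapsed, toy_ref)
        assert r1[0] == r2[0] and r1[1] == r2[1]


class TestStrandFraction:
    @pytest.mark.parametrize(
        "n_sense,n_aligned,expected",
        [(3_687_679, 3_688_594, 99.98), (7, 7, 100.00), (1, 2, 50.00)],
    )
    def test_values(self, n_sense, n_aligned, expected):
        stats = MappingStats(n_cleaned_reads=n_aligned, n_aligned_reads=n_aligned,
                             n_sense=n_sense, n_antisense=n_aligned - n_sense)
        assert strand_fraction(stats) == expected

    def test_zero_aligned_not_computable(self):
        with pytest.raises(ValueError, match="not computable"):
            strand_fraction(MappingStats())


class TestSamInterchange:
    def _write_sam(self, path, ref, rows):
        with open(path, "w") as fh:
            fh.write("@HD\tVN:1.6\n")
            fh.write(f"@SQ\tSN:{ref.id}\tLN:{len(ref)}\n")
            for row in rows:
                fh.write("\t".join(str(x) for x in row) + "\n")
        return path

    @pytest.fixture()
    def ref20(self):
        return _ref("ACGTACGTACGTACGTACGTACGTAC", rid="chrR")

    def test_pos_is_one_based(self, tmp_path, ref20):
        sam = self._write_sam(
            tmp_path / "a.sam", ref20,
            [["q1", 0, "chrR", 4, 255, "20M", "*", 0, 0, ref20.sequence[3:23], "*", "NM:i:0"]],
        )
        records, stats, _ = import_sam(sam, ref20)
        assert (records[0].ref_start, records[0].ref_end) == (3, 23)

    def test_nm_two_discarded(self, tmp_path, ref20):
        sam = self._write_sam(
            tmp_path / "a.sam", ref20,
            [["q1", 0, "chrR", 1, 255, "20M", "*", 0, 0, ref20.sequence[:20], "*", "NM:i:2"]],
        )
        records, stats, n_discarded = import_sam(sam, ref20)
        assert records == [] and n_discarded == 1

    def test_flag16_is_antisense(self, tmp_path, ref20):
        seq = reverse_complement(ref20.sequence[3:23])
        sam = self._write_sam(
            tmp_path / "a.sam", ref20,
            [["q1_x7", 16, "chrR", 4, 255, "20M", "*", 0, 0, seq, "*", "NM:i:0"]],
        )
        records, stats, _ = import_sam(sam, ref20)
        assert records[0].strand == ANTISENSE
        assert records[0].count == 7
        assert records[0].read_sequence == ref20.sequence[3:23]

    def test_clipped_alignment_discarded(self, tmp_path, ref20):
        sam = self._write_sam(
            tmp_path / "a.sam", ref20,
            [["q1", 0, "chrR", 1, 255, "2S18M", "*", 0, 0, ref20.sequence[:20], "*", "NM:i:0"]],
        )
        records, _, n_discarded = import_sam(sam, ref20)
        assert records == [] and n_discarded == 1

    def test_long_indel_discarded(self, tmp_path, ref20):
        sam = self._write_sam(
            tmp_path / "a.sam", ref20,
            [["q1", 0, "chrR", 1, 255, "10M2D10M", "*", 0, 0, ref20.sequence[:20], "*", "NM:i:2"]],
        )
        records, _, n_discarded = import_sam(sam, ref20)
        assert records == [] and n_discarded == 1

    def test_foreign_reference_rejected(self, tmp_path, ref20):
        sam = self._write_sam(
            tmp_path / "a.sam", _ref("ACGT" * 10, rid="other"),
            [["q1", 0, "other", 1, 255, "20M", "*", 0, 0, "ACGTACGTACGTACGTACGT", "*"]],
        )
        with pytest.raises(ValueError, match="other"):
            import_sam(sam, ref20)

    def test_write_then_import_round_trip(self, tmp_path, toy_ref):
        seq = toy_ref.sequence
        collapsed = [CollapsedRead(seq[50:80], 4), CollapsedRead(seq[500:525], 2)]
        records, _ = align_all(collapsed, toy_ref)
        path = tmp_path / "out.sam"
        write_sam(records, toy_ref, path)
        back, stats, n_discarded = import_sam(path, toy_ref)
        assert n_discarded == 0
        assert [(r.ref_start, r.ref_end, r.strand, r.count) for r in back] == [
            (r.ref_start, r.ref_end, r.strand, r.count) for r in records
        ]
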