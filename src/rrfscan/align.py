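"""Placement of short reads on the rDNA reference allowing at most one edit.

"One mismatch or gap" is interpreted literally: the best alignment may carry either a
single substitution or a single 1-nt insertion/deletion, never both. Search is
seed-and-extend with a pigeonhole guarantee: any alignment with <=1 edit contains at
least one edit-free read half, so exact seeding of both halves (via their leading
k-mers) enumerates every candidate placement. Within a candidate the four edit cases
(exact, substitution, 1-nt deletion, 1-nt insertion) are checked directly.

Ties are broken deterministically: lower edit cost, then sense over antisense, then
smaller reference start, then substitution over deletion over insertion. N bases -
in the read or the reference - never match anything and therefore cost an edit.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from ._util import reverse_complement, validate_bases
from .readio import CollapsedRead
from .reference import AnnotatedReference

SENSE = "sense"
ANTISENSE = "antisense"

# edit ranks for tie-breaking
_EXACT, _SUBST, _DELETION, _INSERTION = 0, 1, 2, 3


@dataclass(frozen=True)
class AlignmentRecord:
    read_sequence: str  # as sequenced (not reverse-complemented)
    count: int
    ref_start: int  # 0-based inclusive
    ref_end: int  # 0-based exclusive
    strand: str  # SENSE | ANTISENSE
    n_mismatch: int
    n_gap: int
    cigar: str  # relative to the sense reference orientation

    @property
    def span(self) -> int:
        return self.ref_end - self.ref_start


@dataclass
class MappingStats:
    n_cleaned_reads: int = 0
    n_aligned_reads: int = 0
    n_sense: int = 0
    n_antisense: int = 0


class SeedIndex:
    """Exact k-mer lookup over the sense reference strand.

    Antisense hits are found by querying the reverse complement of the read, so the
    index itself stores one strand only. k-mers containing N are unseedable and are
    skipped; this loses nothing because a window containing N can never be the exact
    half that the pigeonhole argument relies on.
    """

    def __init__(self, reference: AnnotatedReference, k: int = 7):
        if k < 7:
            raise ValueError(f"seed length k={k} is too unspecific; need k >= 7")
        self.reference = reference
        self.sequence = reference.sequence
        self.k = k
        self.ref_has_n = "N" in self.sequence
        table: dict[str, list[int]] = {}
        seq = self.sequence
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            table.setdefault(kmer, []).append(i)
        self._table = {kmer: tuple(pos) for kmer, pos in table.items()}

    def lookup(self, kmer: str) -> tuple[int, ...]:
        return self._table.get(kmer, ())


def build_index(ref: AnnotatedReference, k: int = 7) -> SeedIndex:
    return SeedIndex(ref, k=k)


# ---------------------------------------------------------------------------
# candidate evaluation


def _lcp(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        ca, cb = a[i], b[i]
        if ca != cb or ca == "N":
            return i
    return n


def _lcs(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(1, n + 1):
        ca, cb = a[-i], b[-i]
        if ca != cb or ca == "N":
            return i - 1
    return n


def _hamming(a: str, b: str, limit: int = 1) -> int:
    if a == b and "N" not in a:
        return 0
    m = 0
    for x, y in zip(a, b):
        if x != y or x == "N":
            m += 1
            if m > limit:
                return m
    return m


def _evaluate(ref: str, s: int, q: str):
    """All <=1-edit alignments of q with read start at reference offset s.

    Yields (cost, edit_rank, ref_start, ref_end, n_mismatch, n_gap, cigar).
    Deletion means the read lacks one reference base (reference span len(q)+1);
    insertion means one read base matches nothing (span len(q)-1). Terminal
    deletions are excluded - they would only pad the span, not align anything.
    """
    L, N = len(q), len(ref)
    out = []
    if 0 <= s and s + L <= N:
        mm = _hamming(ref[s : s + L], q)
        if mm == 0:
            out.append((0, _EXACT, s, s + L, 0, 0, f"{L}M"))
        elif mm == 1:
            out.append((1, _SUBST, s, s + L, 1, 0, f"{L}M"))
    if 0 <= s and s + L + 1 <= N:  # deletion: q == w[:j] + w[j+1:], j in 1..L-1
        w = ref[s : s + L + 1]
        p, sx = _lcp(q, w), _lcs(q, w)
        lo, hi = max(1, L - sx), min(p, L - 1)
        if lo <= hi:
            j = lo
            out.append((1, _DELETION, s, s + L + 1, 0, 1, f"{j}M1D{L - j}M"))
    if 0 <= s and L >= 2 and s + L - 1 <= N:  # insertion: w == q[:j] + q[j+1:], j in 0..L-1
        w = ref[s : s + L - 1]
        p, sx = _lcp(q, w), _lcs(q, w)
        lo, hi = max(0, L - 1 - sx), min(p, L - 1)
        if lo <= hi:
            j = lo
            if j == 0:
                cigar = f"1I{L - 1}M"
            elif j == L - 1:
                cigar = f"{L - 1}M1I"
            else:
                cigar = f"{j}M1I{L - 1 - j}M"
            out.append((1, _INSERTION, s, s + L - 1, 0, 1, cigar))
    return out


def _candidates(q: str, index: SeedIndex) -> set[int]:
    """Candidate read-start offsets from exact seeding of both read halves."""
    L, k = len(q), index.k
    m = L // 2
    cands: set[int] = set()
    s1 = q[:k]
    if "N" not in s1:
        cands.update(index.lookup(s1))
    s2 = q[m : m + k]
    if "N" not in s2:
        for p in index.lookup(s2):
            base = p - m
            cands.update((base - 1, base, base + 1))
    N, Lq = len(index.sequence), len(q)
    return {s for s in cands if 0 <= s <= N - (Lq - 1)}


def _full_scan(q: str, ref: str) -> range:
    return range(0, len(ref) - (len(q) - 1) + 1)


def align_read(seq: str, index: SeedIndex) -> AlignmentRecord | None:
    """Best <=1-edit placement of a read on either strand, or None when unmapped."""
    seq = seq.upper()
    validate_bases(seq, what="read")
    ref = index.sequence
    L = len(seq)
    if L > len(ref) or L < 2:
        return None
    best = None  # (cost, strand_rank, ref_start, edit_rank, ref_end, mm, gap, cigar, strand)
    for strand_rank, strand in ((0, SENSE), (1, ANTISENSE)):
        q = seq if strand == SENSE else reverse_complement(seq)
        if not index.ref_has_n and "N" not in q:
            i = ref.find(q)
            if i >= 0:
                # leftmost exact hit: optimal for this strand, and cost 0 overall
                cand = (0, strand_rank, i, _EXACT, i + L, 0, 0, f"{L}M", strand)
                if best is None or cand[:4] < best[:4]:
                    best = cand
                if strand == SENSE:
                    break  # leftmost sense exact match cannot be beaten
                continue
        starts = _candidates(q, index) if L >= 2 * index.k else _full_scan(q, ref)
        for s in sorted(starts):
            for cost, rank, rs, re_, mm, gap, cigar in _evaluate(ref, s, q):
                cand = (cost, strand_rank, rs, rank, re_, mm, gap, cigar, strand)
                if best is None or cand[:4] < best[:4]:
                    best = cand
    if best is None:
        return None
    cost, _, rs, _, re_, mm, gap, cigar, strand = best
    return AlignmentRecord(
        read_sequence=seq, count=1, ref_start=rs, ref_end=re_,
        strand=strand, n_mismatch=mm, n_gap=gap, cigar=cigar,
    )


def align_all(
    collapsed: Sequence[CollapsedRead],
    ref: AnnotatedReference,
    k: int = 7,
    keep_antisense: bool = True,
    index: SeedIndex | None = None,
) -> tuple[list[AlignmentRecord], MappingStats]:
    """Align each unique sequence once; statistics are weighted by duplicate count."""
    if index is None:
        index = SeedIndex(ref, k=k)
    records: list[AlignmentRecord] = []
    stats = MappingStats()
    for cr in collapsed:
        stats.n_cleaned_reads += cr.count
        rec = align_read(cr.sequence, index)
        if rec is None:
            continue
        if rec.strand == ANTISENSE and not keep_antisense:
            continue
        rec = AlignmentRecord(**{**rec.__dict__, "count": cr.count})
        records.append(rec)
        stats.n_aligned_reads += cr.count
        if rec.strand == SENSE:
            stats.n_sense += cr.count
        else:
            stats.n_antisense += cr.count
    return records, stats


def strand_fraction(stats: MappingStats) -> float:
    """Percentage of aligned reads on the sense strand (two decimals, half-up)."""
    if stats.n_aligned_reads == 0:
        raise ValueError("no aligned reads; strand fraction is not computable")
    from ._util import percent

    return percent(stats.n_sense, stats.n_aligned_reads, 2)


# ---------------------------------------------------------------------------
# SAM interchange

_COUNT_RE = re.compile(r"_x(\d+)$")
_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def write_sam(
    records: Iterable[AlignmentRecord], ref: AnnotatedReference, path: str | Path
) -> None:
    """Write internal alignments as SAM (sense coordinates, NM tag, unmapped omitted)."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": ref.id, "LN": len(ref)}],
        "PG": [{"ID": "rrfscan", "PN": "rrfscan"}],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for i, rec in enumerate(records, 1):
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"seq{i}_x{rec.count}"
            a.flag = 16 if rec.strand == ANTISENSE else 0
            a.reference_id = 0
            a.reference_start = rec.ref_start
            a.mapping_quality = 255
            a.cigarstring = rec.cigar
            a.query_sequence = (
                rec.read_sequence if rec.strand == SENSE else reverse_complement(rec.read_sequence)
            )
            a.set_tag("NM", rec.n_mismatch + rec.n_gap)
            out.write(a)


def import_sam(
    sam_source: str | Path, ref: AnnotatedReference
) -> tuple[list[AlignmentRecord], MappingStats, int]:
    """Convert external SAM alignments, enforcing the same <=1-edit contract.

    Records with NM >= 2, an indel longer than 1 nt, both a mismatch and a gap, or any
    clipping are discarded. Duplicate counts are recovered from the ``_x<count>``
    read-name convention when present. Returns (records, stats, n_discarded).
    """
    import pysam

    records: list[AlignmentRecord] = []
    stats = MappingStats()
    n_discarded = 0
    with pysam.AlignmentFile(str(sam_source), "r", check_sq=False) as sam:
        names = set(sam.references or ())
        if names and ref.id not in names:
            raise ValueError(
                f"SAM references {sorted(names)} do not include reference {ref.id!r}"
            )
        for a in sam:
            m = _COUNT_RE.search(a.query_name or "")
            count = int(m.group(1)) if m else 1
            stats.n_cleaned_reads += count
            if a.is_unmapped:
                continue
            if a.reference_name != ref.id:
                raise ValueError(
                    f"alignment on {a.reference_name!r}, reference is {ref.id!r}"
                )
            try:
                cig = a.cigartuples or []
            except ValueError:
                n_discarded += 1
                continue
            if any(op in (4, 5) for op, _ in cig):  # soft/hard clip
                n_discarded += 1
                continue
            gap_bases = sum(ln for op, ln in cig if op in (1, 2))
            n_gap_ops = sum(1 for op, ln in cig if op in (1, 2))
            if any(op in (1, 2) and ln > 1 for op, ln in cig):
                n_discarded += 1
                continue
            nm = a.get_tag("NM") if a.has_tag("NM") else gap_bases
            if nm >= 2:
                n_discarded += 1
                continue
            n_mismatch = int(nm) - gap_bases
            if n_mismatch < 0 or n_mismatch + n_gap_ops > 1:
                n_discarded += 1
                continue
            seq = a.query_sequence or ""
            strand = ANTISENSE if a.is_reverse else SENSE
            if strand == ANTISENSE:
                seq = reverse_complement(seq)
            rec = AlignmentRecord(
                read_sequence=seq, count=count,
                ref_start=a.reference_start, ref_end=a.reference_end,
                strand=strand, n_mismatch=n_mismatch, n_gap=n_gap_ops,
                cigar=a.cigarstring or "",
            )
            records.append(rec)
            stats.n_aligned_reads += count
            if strand == SENSE:
                stats.n_sense += count
            else:
                stats.n_antisense += count
    return records, stats, n_discarded
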