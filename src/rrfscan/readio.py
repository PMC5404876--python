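"""Raw read input, minimal sRNA-seq cleaning, QC statistics, and duplicate collapsing.

Cleaning is deliberately minimal: 3' adapter trimming, a length floor (default 15 nt,
the only cleaning rule carried into every downstream statistic), and an N-content
filter. Base-quality filtering is off by default - Q20 is reported as a statistic,
not enforced as a filter.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

PHRED_OFFSET = 33
_Q20_CHAR = chr(20 + PHRED_OFFSET)


class FastqParseError(ValueError):
    """Malformed FASTQ input; carries the 0-based index of the offending record."""

    def __init__(self, message: str, record_index: int):
        super().__init__(f"record {record_index}: {message}")
        self.record_index = record_index


@dataclass
class RawRead:
    id: str
    sequence: str
    qualities: str | None = None  # Phred+33 string, same length as sequence

    def __post_init__(self) -> None:
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.id!r}: quality length {len(self.qualities)} != "
                f"sequence length {len(self.sequence)}"
            )

    def phred(self) -> np.ndarray:
        if self.qualities is None:
            raise ValueError(f"read {self.id!r} has no quality scores")
        return np.frombuffer(self.qualities.encode(), dtype=np.uint8).astype(int) - PHRED_OFFSET


@dataclass(frozen=True)
class CollapsedRead:
    sequence: str
    count: int


@dataclass
class QCStats:
    n_raw: int = 0
    n_cleaned: int = 0
    q20_percent: float | None = None
    length_histogram: dict[int, int] = field(default_factory=dict)


def _open_text(path: str | Path):
    path = Path(path)
    return gzip.open(path, "rt") if path.suffix == ".gz" else open(path)


def read_fastq(path: str | Path) -> Iterator[RawRead]:
    with _open_text(path) as fh:
        it = FastqGeneralIterator(fh)
        i = 0
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqParseError(str(exc), i) from exc
            if len(seq) != len(qual):
                raise FastqParseError(
                    f"sequence length {len(seq)} != quality length {len(qual)}", i
                )
            yield RawRead(id=title.split()[0], sequence=seq.upper(), qualities=qual)
            i += 1


def read_fasta(path: str | Path) -> Iterator[RawRead]:
    with _open_text(path) as fh:
        for title, seq in SimpleFastaParser(fh):
            yield RawRead(id=title.split()[0], sequence=seq.upper())


def read_sequences(path: str | Path) -> Iterator[RawRead]:
    """Dispatch on file suffix: .fastq/.fq (optionally .gz) vs FASTA."""
    stem = str(path).removesuffix(".gz")
    if stem.endswith((".fastq", ".fq")):
        return read_fastq(path)
    return read_fasta(path)


# ---------------------------------------------------------------------------
# Cleaning


def _mismatches(a: str, b: str, limit: int) -> int:
    m = 0
    for x, y in zip(a, b):
        if x != y:
            m += 1
            if m > limit:
                return m
    return m


def find_adapter(seq: str, adapter: str, seed_len: int = 8, max_mismatch: int = 1) -> int:
    """Leftmost position where a >=seed_len prefix of the adapter matches with
    <=max_mismatch mismatches; -1 when absent."""
    if len(adapter) < seed_len:
        raise ValueError(f"adapter shorter than seed length {seed_len}")
    for i in range(len(seq) - seed_len + 1):
        m = min(len(adapter), len(seq) - i)
        if _mismatches(seq[i : i + m], adapter[:m], max_mismatch) <= max_mismatch:
            return i
    return -1


def clean_reads(
    reads: Iterable[RawRead],
    adapter: str | None = None,
    min_len: int = 15,
    min_mean_q: float | None = None,
    seed_len: int = 8,
    max_adapter_mismatch: int = 1,
    max_n_fraction: float = 0.1,
) -> tuple[list[RawRead], QCStats]:
    """Trim the 3' adapter, drop short / N-rich / (optionally) low-quality reads.

    Untrimmed reads are kept: with total-RNA input many inserts are long enough that
    the sequencer never reads into the adapter. Returns the surviving reads and QC
    statistics computed over them (Q20 is None for FASTA input).
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    kept: list[RawRead] = []
    n_raw = 0
    q20_num = 0
    q20_den = 0
    hist: Counter[int] = Counter()
    for read in reads:
        n_raw += 1
        seq, qual = read.sequence, read.qualities
        if adapter is not None:
            pos = find_adapter(seq, adapter, seed_len, max_adapter_mismatch)
            if pos >= 0:
                seq = seq[:pos]
                qual = qual[:pos] if qual is not None else None
        if len(seq) < min_len:
            continue
        if seq.count("N") > max_n_fraction * len(seq):
            continue
        if min_mean_q is not None:
            if qual is None:
                raise ValueError("min_mean_q set but input has no quality scores")
            if np.mean(np.frombuffer(qual.encode(), np.uint8)) - PHRED_OFFSET < min_mean_q:
                continue
        kept.append(RawRead(id=read.id, sequence=seq, qualities=qual))
        hist[len(seq)] += 1
        if qual is not None:
            q20_den += len(qual)
            q20_num += sum(1 for c in qual if c >= _Q20_CHAR)
    q20 = None
    if q20_den:
        from ._util import round_half_up

        q20 = round_half_up(100.0 * q20_num / q20_den, 1)
    return kept, QCStats(
        n_raw=n_raw, n_cleaned=len(kept), q20_percent=q20,
        length_histogram=dict(sorted(hist.items())),
    )


def q20_percent(reads: Iterable[RawRead]) -> float:
    """Percentage of bases with Phred >= 20, half-up rounded to one decimal."""
    num = den = 0
    for read in reads:
        if read.qualities is None:
            raise ValueError(
                f"read {read.id!r} has no quality scores; Q20 is not computable from FASTA"
            )
        den += len(read.qualities)
        num += sum(1 for c in read.qualities if c >= _Q20_CHAR)
    if den == 0:
        raise ValueError("no bases; Q20 is not computable")
    from ._util import round_half_up

    return round_half_up(100.0 * num / den, 1)


# ---------------------------------------------------------------------------
# Collapsing


def collapse_reads(reads: Iterable[RawRead]) -> list[CollapsedRead]:
    """One entry per distinct sequence, sorted by descending count then sequence."""
    counts = Counter(r.sequence for r in reads)
    return [
        CollapsedRead(sequence=s, count=c)
        for s, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def write_collapsed_fasta(collapsed: Iterable[CollapsedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rank, cr in enumerate(collapsed, 1):
            fh.write(f">seq{rank}_x{cr.count}\n{cr.sequence}\n")


def write_collapsed_tsv(collapsed: Iterable[CollapsedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence\tcount\n")
        for cr in collapsed:
            fh.write(f"{cr.sequence}\t{cr.count}\n")
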