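"""Synthetic sRNA-seq libraries with ground truth, for testing every pipeline stage.

The generator emulates the statistical structure the analysis assumes in real total-RNA
sRNA-seq of an arthropod:

* terminus-anchored 1-bp length ladders at designated gene boundaries (the signal);
* a uniform-degradation background: random breakpoints along the rDNA, fragment
  lengths ~15-40 nt (the null);
* heavy PCR duplication of a few sequences;
* near-exclusive sense-strand origin (default antisense fraction 2e-4);
* a small per-base substitution error rate, constant Phred-40 qualities.

Background fragments are drawn length-first (length ~ U[15,40], then start uniform
over all placements that fit), which keeps both fragment endpoints uniformly
distributed along the interior of the reference - the property the degradation null
asserts - without piling clipped fragments onto the reference ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._util import reverse_complement
from .readio import RawRead
from .reference import AnnotatedReference, Region, infer_role
from .series import FIVE_PRIME, THREE_PRIME, RRFSeries

#: Toy rDNA transcribed unit: realistic proportions at roughly half scale
#: (5.8S kept at its natural ~160 nt; 18S and 28S scaled down together).
DEFAULT_REGION_LENGTHS: dict[str, int] = {
    "18S": 1200,
    "ITS1": 170,
    "5.8S": 160,
    "ITS2": 190,
    "28S": 2230,
}

_CANONICAL_ORDER = ("18S", "ITS1", "5.8S", "ITS2", "28S")


class SyntheticConfigError(ValueError):
    pass


@dataclass(frozen=True)
class LadderSpec:
    region_name: str
    terminus: str  # FIVE_PRIME | THREE_PRIME
    length_min: int
    length_max: int
    count_per_length: float  # Poisson mean reads per length

    def __post_init__(self) -> None:
        if not (15 <= self.length_min <= self.length_max):
            raise SyntheticConfigError(
                f"ladder {self.region_name}:{self.terminus}: lengths must satisfy "
                f"15 <= min <= max, got [{self.length_min}, {self.length_max}]"
            )
        if self.count_per_length <= 0:
            raise SyntheticConfigError("count_per_length must be > 0")
        if self.terminus not in (FIVE_PRIME, THREE_PRIME):
            raise SyntheticConfigError(f"unknown terminus {self.terminus!r}")

    @property
    def ladder_id(self) -> str:
        return f"{self.region_name}:{self.terminus}"


@dataclass
class SyntheticConfig:
    reference: AnnotatedReference | None = None  # None -> built-in toy rDNA
    ladders: Sequence[LadderSpec] = field(default_factory=tuple)
    n_background: int = 10_000
    antisense_fraction: float = 2e-4  # mirrors a 99.98% sense library
    error_rate: float = 1e-3  # per-base substitution probability
    dup_sequences: Sequence[tuple[str, int]] = field(default_factory=tuple)
    background_length: tuple[int, int] = (15, 40)
    seed: int = 0

    def __post_init__(self) -> None:
        for p, label in ((self.antisense_fraction, "antisense_fraction"),
                         (self.error_rate, "error_rate")):
            if not 0.0 <= p <= 1.0:
                raise SyntheticConfigError(f"{label} must be in [0,1], got {p}")
        if self.n_background < 0:
            raise SyntheticConfigError("n_background must be >= 0")
        lo, hi = self.background_length
        if not (1 <= lo <= hi):
            raise SyntheticConfigError(f"invalid background length range [{lo},{hi}]")


def make_toy_reference(
    region_lengths: dict[str, int] | None = None, seed: int = 0
) -> AnnotatedReference:
    """Random reference with contiguous regions in canonical 18S..28S order."""
    lengths = dict(DEFAULT_REGION_LENGTHS if region_lengths is None else region_lengths)
    for name, L in lengths.items():
        if L < 30:
            raise SyntheticConfigError(f"region {name!r} length {L} < 30 nt")
    order = [n for n in _CANONICAL_ORDER if n in lengths]
    order += [n for n in lengths if n not in order]  # extra names appended as given
    rng = np.random.default_rng(seed)
    total = sum(lengths.values())
    seq = "".join(rng.choice(list("ACGT"), size=total))
    regions = []
    pos = 0
    for name in order:
        regions.append(Region(name=name, start=pos, end=pos + lengths[name],
                              role=infer_role(name)))
        pos += lengths[name]
    return AnnotatedReference(id="toy_rDNA", sequence=seq, regions=tuple(regions))


_BASES = np.array(list("ACGT"))


def _mutate(seq: str, positions: np.ndarray, rng: np.random.Generator) -> str:
    s = list(seq)
    for p in positions:
        alternatives = [b for b in "ACGT" if b != s[p]]
        s[p] = alternatives[rng.integers(0, 3)]
    return "".join(s)


def simulate_library(cfg: SyntheticConfig) -> tuple[list[RawRead], pd.DataFrame, AnnotatedReference]:
    """Generate reads plus a per-read truth table.

    Returns (reads, truth, reference). Truth columns: read_id, origin
    (ladder | background | duplicate), ladder_id, ref_start, ref_end, strand.
    Deterministic for a fixed config (including seed).
    """
    ref = cfg.reference if cfg.reference is not None else make_toy_reference(seed=cfg.seed)
    rng = np.random.default_rng(cfg.seed)
    refseq = ref.sequence
    n = len(refseq)
    reads: list[RawRead] = []
    truth_rows: list[tuple] = []
    fragment_by_id: dict[str, tuple[str, int, int]] = {}

    def _emit(seq: str, start: int, end: int, origin: str, ladder_id: str) -> None:
        if cfg.error_rate > 0:
            k = rng.binomial(len(seq), cfg.error_rate)
            if k:
                pos = rng.choice(len(seq), size=k, replace=False)
                seq = _mutate(seq, pos, rng)
        strand = "sense"
        if cfg.antisense_fraction > 0 and rng.random() < cfg.antisense_fraction:
            seq = reverse_complement(seq)
            strand = "antisense"
        rid = f"sim{len(reads):07d}"
        reads.append(RawRead(id=rid, sequence=seq, qualities="I" * len(seq)))
        truth_rows.append((rid, origin, ladder_id, start, end, strand))

    # planted ladders
    for spec in cfg.ladders:
        region = ref.region_by_name(spec.region_name)
        if spec.length_max > region.length:
            raise SyntheticConfigError(
                f"ladder {spec.ladder_id}: length {spec.length_max} exceeds region "
                f"length {region.length}"
            )
        for L in range(spec.length_min, spec.length_max + 1):
            if spec.terminus == FIVE_PRIME:
                start, end = region.start, region.start + L
            else:
                start, end = region.end - L, region.end
            frag = refseq[start:end]
            fragment_by_id[f"{spec.ladder_id}:{L}"] = (frag, start, end)
            for _ in range(rng.poisson(spec.count_per_length)):
                _emit(frag, start, end, "ladder", spec.ladder_id)

    # uniform-degradation background: length first, then any start that fits
    lo, hi = cfg.background_length
    hi = min(hi, n)
    lo = min(lo, hi)
    if cfg.n_background:
        lens = rng.integers(lo, hi + 1, size=cfg.n_background)
        starts = (rng.random(cfg.n_background) * (n - lens + 1)).astype(np.int64)
        for L, s in zip(lens.tolist(), starts.tolist()):
            _emit(refseq[s : s + L], s, s + L, "background", "")

    # PCR duplication: exact copies of a template (no fresh errors)
    for key, factor in cfg.dup_sequences:
        if key in fragment_by_id:
            frag, start, end = fragment_by_id[key]
        else:
            frag, start, end = key, -1, -1
        for _ in range(int(factor)):
            rid = f"sim{len(reads):07d}"
            reads.append(RawRead(id=rid, sequence=frag, qualities="I" * len(frag)))
            truth_rows.append((rid, "duplicate", key if start >= 0 else "", start, end, "sense"))

    truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "origin", "ladder_id", "ref_start", "ref_end", "strand"],
    )
    return reads, truth, ref


def write_fastq(reads: Sequence[RawRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.qualities or 'I' * len(r.sequence)}\n")


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# recovery assessment


def truth_compare(
    truth: pd.DataFrame,
    series: Sequence[RRFSeries],
    ref: AnnotatedReference,
    min_run: int = 3,
    min_total: int = 10,
) -> dict:
    """Compare called series against planted ladders.

    Per planted ladder: whether its anchor was recovered exactly, the recovered
    ladder run vs the planted length range, and count recall. Globally: precision
    and recall of called series against the ladders large enough to be callable;
    a planted ladder below the calling thresholds is reported as missed-below-
    threshold, not as a pipeline failure.
    """
    called = {(s.region_name, s.terminus): s for s in series if s.called}
    planted = truth[truth["origin"].isin(["ladder", "duplicate"]) & (truth["ladder_id"] != "")]
    per_ladder = []
    eligible = set()
    expected_anchors: dict[tuple[str, str], int] = {}
    for ladder_id, grp in planted.groupby("ladder_id"):
        if ":" not in ladder_id:
            continue
        region_name, terminus = ladder_id.split(":")[:2]
        region = ref.region_by_name(region_name)
        expected_anchor = region.start if terminus == FIVE_PRIME else region.end
        lengths = (grp["ref_end"] - grp["ref_start"]).astype(int)
        planted_range = int(lengths.max() - lengths.min() + 1)
        planted_total = int(len(grp))
        key = (region_name, terminus)
        expected_anchors[key] = expected_anchor
        s = called.get(key)
        callable_ = planted_total >= min_total and planted_range >= min_run
        if callable_:
            eligible.add(key)
        per_ladder.append(
            dict(
                ladder_id=ladder_id,
                planted_total=planted_total,
                planted_range=planted_range,
                callable_at_thresholds=callable_,
                called=s is not None,
                anchor_recovered=(s is not None and s.anchor == expected_anchor),
                recovered_run=(s.max_run if s is not None else 0),
                count_recall=(s.total_count / planted_total if s is not None else 0.0),
            )
        )
    tp = sum(
        1 for key, s in called.items()
        if key in eligible and s.anchor == expected_anchors.get(key)
    )
    precision = tp / len(called) if called else 1.0
    recall = tp / len(eligible) if eligible else 1.0
    return dict(
        per_ladder=per_ladder,
        n_called=len(called),
        n_planted_eligible=len(eligible),
        precision=precision,
        recall=recall,
    )
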