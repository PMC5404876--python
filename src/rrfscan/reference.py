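"""Annotated rDNA reference: sequence plus named, ordered, non-overlapping regions.

The reference is the transcribed rDNA unit (canonically 18S-ITS1-5.8S-ITS2-28S on the
sense strand). Regions carry a role: ``gene`` for mature rRNA genes whose boundaries
define rRF5/rRF3 termini, ``spacer`` for transcribed spacers. All internal coordinates
are 0-based half-open; 1-based coordinates appear only in human-readable reports.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser

from ._util import validate_bases

GENE = "gene"
SPACER = "spacer"

#: Region-name prefixes treated as spacers when no explicit role is given.
#: ITS: internal transcribed spacers; ETS/NTS/IGS: external/non-transcribed spacers.
SPACER_PREFIXES = ("ITS", "ETS", "NTS", "IGS")


class ReferenceValidationError(ValueError):
    """Raised when a reference or its region annotation violates an invariant."""


def infer_role(name: str) -> str:
    return SPACER if name.upper().startswith(SPACER_PREFIXES) else GENE


@dataclass(frozen=True)
class Region:
    """A named half-open interval [start, end) on the reference."""

    name: str
    start: int
    end: int
    role: str = GENE

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ReferenceValidationError(
                f"region {self.name!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.role not in (GENE, SPACER):
            raise ReferenceValidationError(f"region {self.name!r}: unknown role {self.role!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RegionAssignment:
    """Result of locating an interval: a containing region, a span, or a gap."""

    kind: str  # "region" | "spanning" | "unannotated"
    region: Region | None = None
    overlapped: tuple[Region, ...] = ()

    @property
    def name(self) -> str:
        if self.kind == "region":
            assert self.region is not None
            return self.region.name
        if self.kind == "spanning":
            return "spanning:" + "|".join(r.name for r in self.overlapped)
        return "unannotated"


@dataclass(frozen=True)
class AnnotatedReference:
    id: str
    sequence: str
    regions: tuple[Region, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ReferenceValidationError("reference sequence is empty")
        validate_bases(self.sequence, what=f"reference {self.id!r}")
        object.__setattr__(self, "regions", tuple(sorted(self.regions, key=lambda r: r.start)))
        self._validate_regions()

    def _validate_regions(self) -> None:
        n = len(self.sequence)
        offenders = []
        seen: set[str] = set()
        prev: Region | None = None
        for r in self.regions:
            if r.name in seen:
                offenders.append(f"duplicate name {r.name!r}")
            seen.add(r.name)
            if r.end > n:
                offenders.append(f"{r.name!r} [{r.start},{r.end}) exceeds reference length {n}")
            if prev is not None and r.start < prev.end:
                offenders.append(
                    f"{prev.name!r} [{prev.start},{prev.end}) overlaps {r.name!r} [{r.start},{r.end})"
                )
            prev = r
        if offenders:
            raise ReferenceValidationError("invalid region annotation: " + "; ".join(offenders))

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def genes(self) -> tuple[Region, ...]:
        return tuple(r for r in self.regions if r.role == GENE)

    def region_by_name(self, name: str) -> Region:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(f"no region named {name!r}")

    def region_at(self, start: int, end: int) -> RegionAssignment:
        """Assign the interval [start, end) to the unique fully-containing region,
        to ``spanning`` (listing every overlapped region), or to ``unannotated``."""
        if start >= end:
            raise ValueError(f"empty interval [{start}, {end})")
        if start < 0 or end > len(self.sequence):
            raise ValueError(f"interval [{start}, {end}) outside reference of length {len(self)}")
        overlapped = tuple(r for r in self.regions if r.start < end and start < r.end)
        if not overlapped:
            return RegionAssignment("unannotated")
        if len(overlapped) == 1 and overlapped[0].start <= start and end <= overlapped[0].end:
            return RegionAssignment("region", region=overlapped[0])
        return RegionAssignment("spanning", overlapped=overlapped)


# ---------------------------------------------------------------------------
# I/O


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_single_fasta(path: str | Path) -> tuple[str, str]:
    """Read the one and only record of a FASTA file; error on any other count."""
    with _open_text(path) as fh:
        records = [(title.split()[0], seq.upper()) for title, seq in SimpleFastaParser(fh)]
    if len(records) != 1:
        raise ReferenceValidationError(
            f"reference FASTA {path} must contain exactly one record, found {len(records)}"
        )
    return records[0]


def regions_from_bed(path: str | Path, ref_id: str) -> list[Region]:
    """BED intervals (0-based half-open; name in column 4, optional role in column 5)."""
    regions = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 4:
                raise ReferenceValidationError(
                    f"{path}:{lineno}: BED needs >=4 columns (chrom start end name)"
                )
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            if chrom != ref_id:
                raise ReferenceValidationError(
                    f"{path}:{lineno}: interval on {chrom!r}, reference is {ref_id!r}"
                )
            role = fields[4] if len(fields) > 4 and fields[4] in (GENE, SPACER) else infer_role(name)
            regions.append(Region(name=name, start=start, end=end, role=role))
    return regions


def regions_from_gff3(path: str | Path, ref_id: str) -> list[Region]:
    """GFF3 features (1-based inclusive, converted to 0-based half-open).

    The region name comes from the Name attribute, falling back to ID; the role from
    the feature type when it is literally ``gene``/``spacer``, else inferred from the name.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    regions = []
    for feat in db.all_features(order_by="start"):
        if feat.seqid != ref_id:
            raise ReferenceValidationError(
                f"{path}: feature on {feat.seqid!r}, reference is {ref_id!r}"
            )
        name = (feat.attributes.get("Name") or feat.attributes.get("ID") or [feat.id])[0]
        role = feat.featuretype if feat.featuretype in (GENE, SPACER) else infer_role(name)
        regions.append(Region(name=name, start=feat.start - 1, end=feat.end, role=role))
    return regions


def load_reference(fasta_source: str | Path, annotation_source: str | Path) -> AnnotatedReference:
    """Load a single-record FASTA plus a BED or GFF3 annotation into one validated object."""
    ref_id, seq = read_single_fasta(fasta_source)
    suffix = Path(str(annotation_source).removesuffix(".gz")).suffix.lower()
    if suffix in (".gff", ".gff3"):
        regions = regions_from_gff3(annotation_source, ref_id)
    else:
        regions = regions_from_bed(annotation_source, ref_id)
    return AnnotatedReference(id=ref_id, sequence=seq, regions=tuple(regions))


def write_bed(ref_or_regions: AnnotatedReference | Iterable[Region], path: str | Path,
              ref_id: str | None = None) -> None:
    if isinstance(ref_or_regions, AnnotatedReference):
        regions: Sequence[Region] = ref_or_regions.regions
        ref_id = ref_or_regions.id
    else:
        regions = list(ref_or_regions)
        if ref_id is None:
            raise ValueError("ref_id required when writing bare regions")
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{ref_id}\t{r.start}\t{r.end}\t{r.name}\t{r.role}\n")
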