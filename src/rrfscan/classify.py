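"""Region-of-origin assignment and terminus classification of aligned fragments.

A fragment whose 5' end coincides with a gene's 5' boundary (within a tolerance,
default 0 nt - "precisely") is an rRF5; one whose 3' end coincides with the gene's
3' boundary is an rRF3; other fragments inside a single region are body fragments.
Fragments crossing a region boundary are "spanning" and belong to no terminus class.
rRF5 is checked before rRF3, so a fragment covering an entire short gene is classed
rRF5 and additionally flagged full-length.

Antisense fragments are classified against the same sense-strand boundaries but
flagged, and are excluded from series detection by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .align import ANTISENSE, AlignmentRecord
from .reference import GENE, AnnotatedReference

RRF5 = "rRF5"
RRF3 = "rRF3"
BODY = "body"
SPANNING = "spanning"
UNANNOTATED = "unannotated"

TERMINUS_CLASSES = (RRF5, RRF3, BODY, SPANNING, UNANNOTATED)


@dataclass(frozen=True)
class FragmentAnnotation:
    region_name: str  # region name, or "spanning:..." / "unannotated"
    terminus_class: str
    offset5: int | None = None  # ref_start - region.start
    offset3: int | None = None  # region.end - ref_end
    full_length: bool = False
    antisense: bool = False


def classify_alignment(
    aln: AlignmentRecord, ref: AnnotatedReference, tol: int = 0
) -> FragmentAnnotation:
    if tol < 0:
        raise ValueError("tol must be >= 0")
    assignment = ref.region_at(aln.ref_start, aln.ref_end)
    antisense = aln.strand == ANTISENSE
    if assignment.kind == "unannotated":
        return FragmentAnnotation(UNANNOTATED, UNANNOTATED, antisense=antisense)
    if assignment.kind == "spanning":
        return FragmentAnnotation(assignment.name, SPANNING, antisense=antisense)
    region = assignment.region
    assert region is not None
    off5 = aln.ref_start - region.start
    off3 = region.end - aln.ref_end
    cls = BODY
    full = False
    if region.role == GENE:
        if abs(off5) <= tol:
            cls = RRF5
            full = abs(off3) <= tol
        elif abs(off3) <= tol:
            cls = RRF3
    return FragmentAnnotation(
        region_name=region.name, terminus_class=cls,
        offset5=off5, offset3=off3, full_length=full, antisense=antisense,
    )


def classify_all(
    alignments: Sequence[AlignmentRecord], ref: AnnotatedReference, tol: int = 0
) -> list[tuple[AlignmentRecord, FragmentAnnotation]]:
    return [(aln, classify_alignment(aln, ref, tol)) for aln in alignments]


def region_counts(
    pairs: Iterable[tuple[AlignmentRecord, FragmentAnnotation]],
    ref: AnnotatedReference | None = None,
) -> tuple[pd.DataFrame, float | None]:
    """Count-weighted (region, terminus class) table plus the gene-derived fraction.

    The gene fraction is the percentage of aligned read counts assigned wholly to
    gene regions; spanning and unannotated counts sit in the denominator only.
    Returns (table, gene_fraction_percent); the fraction is None for empty input.
    """
    from .reference import infer_role

    if ref is not None:
        gene_names = {r.name for r in ref.regions if r.role == GENE}
        is_gene = gene_names.__contains__
    else:
        is_gene = lambda name: infer_role(name) == GENE  # noqa: E731

    rows: dict[tuple[str, str], int] = {}
    total = 0
    gene_total = 0
    for aln, ann in pairs:
        key = (ann.region_name, ann.terminus_class)
        rows[key] = rows.get(key, 0) + aln.count
        total += aln.count
        if ann.terminus_class in (RRF5, RRF3, BODY) and is_gene(ann.region_name):
            gene_total += aln.count
    table = pd.DataFrame(
        [(region, cls, count) for (region, cls), count in sorted(rows.items())],
        columns=["region", "terminus_class", "count"],
    )
    if total == 0:
        return table, None
    from ._util import percent

    return table, percent(gene_total, total, 1)
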