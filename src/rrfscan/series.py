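"""Terminus-anchored fragment series: 1-bp length ladders and terminal enrichment.

An rRF series is the set of fragments sharing one anchored terminus (a gene boundary
at tolerance 0) whose opposite end varies, producing a histogram of fragment lengths.
The ladder statistic is the longest run of consecutive integer lengths each observed
at depth >= min_count. A series is *called* when its ladder run and total depth clear
thresholds (defaults: run >= 3, total >= 10), so neither a lone fragment nor a pair
can ever be a series.

Terminal enrichment is tested against a uniform-degradation null: if fragments arose
from random breakpoints, the anchored coordinate of a fragment whose terminus lies in
a gene of G positions is uniform over those G positions, so the boundary count is
Binomial(n, window/G) with window = 1 + 2*tol clipped at region edges. The one-sided
binomial tail gives the p-value; Benjamini-Hochberg correction is applied across
(gene, terminus) pairs in the report.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .align import SENSE, AlignmentRecord
from .classify import RRF3, RRF5, FragmentAnnotation
from .reference import GENE, AnnotatedReference, Region

FIVE_PRIME = "5p"
THREE_PRIME = "3p"


@dataclass
class RRFSeries:
    region_name: str
    terminus: str  # FIVE_PRIME | THREE_PRIME
    anchor: int  # reference coordinate shared by members (gene start or end)
    length_histogram: dict[int, int] = field(default_factory=dict)
    total_count: int = 0
    max_run: int = 0
    called: bool = False


@dataclass(frozen=True)
class EnrichmentResult:
    region_name: str
    terminus: str
    observed_terminal_count: int
    total_region_count: int
    n_start_positions: int
    expected_fraction: float
    fold_enrichment: float
    p_value: float


def max_ladder_run(hist: Mapping[int, int], min_count: int = 1) -> int:
    """Longest run of consecutive lengths L, L+1, ..., each with count >= min_count."""
    lengths = sorted(L for L, c in hist.items() if c >= min_count)
    best = run = 0
    prev = None
    for L in lengths:
        run = run + 1 if prev is not None and L == prev + 1 else 1
        best = max(best, run)
        prev = L
    return best


def group_by_anchor(
    classified: Iterable[tuple[AlignmentRecord, FragmentAnnotation]],
    ref: AnnotatedReference,
    min_count: int = 1,
    include_antisense: bool = False,
) -> list[RRFSeries]:
    """One series per (gene, terminus) with >= 1 terminal member.

    rRF5 members share the gene-start coordinate, rRF3 members the gene-end
    coordinate; fragment length is the reference span (so a 1-nt-deletion variant of
    a 30-nt fragment still counts as reference length 30, keeping anchors exact).
    A full-length fragment (both offsets within tolerance) contributes to both series.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    hists: dict[tuple[str, str], dict[int, int]] = {}

    def _add(region: str, terminus: str, span: int, count: int) -> None:
        h = hists.setdefault((region, terminus), {})
        h[span] = h.get(span, 0) + count

    for aln, ann in classified:
        if ann.antisense and not include_antisense:
            continue
        if ann.terminus_class == RRF5:
            _add(ann.region_name, FIVE_PRIME, aln.span, aln.count)
            if ann.full_length:
                _add(ann.region_name, THREE_PRIME, aln.span, aln.count)
        elif ann.terminus_class == RRF3:
            _add(ann.region_name, THREE_PRIME, aln.span, aln.count)

    out = []
    for (region_name, terminus), hist in sorted(hists.items()):
        region = ref.region_by_name(region_name)
        anchor = region.start if terminus == FIVE_PRIME else region.end
        out.append(
            RRFSeries(
                region_name=region_name, terminus=terminus, anchor=anchor,
                length_histogram=dict(sorted(hist.items())),
                total_count=sum(hist.values()),
                max_run=max_ladder_run(hist, min_count),
            )
        )
    return out


def call_series(
    series: Sequence[RRFSeries], min_run: int = 3, min_total: int = 10
) -> list[RRFSeries]:
    """Flag series with a ladder run >= min_run and depth >= min_total; sort by depth."""
    if min_run < 1 or min_total < 1:
        raise ValueError("min_run and min_total must be >= 1")
    flagged = [
        replace_called(s, s.max_run >= min_run and s.total_count >= min_total) for s in series
    ]
    return sorted(flagged, key=lambda s: (-s.total_count, s.region_name, s.terminus))


def replace_called(s: RRFSeries, called: bool) -> RRFSeries:
    return replace(s, called=called)


# ---------------------------------------------------------------------------
# enrichment against the uniform-degradation null


def anchor_table(
    alignments: Iterable[AlignmentRecord], region: Region, terminus: str
) -> np.ndarray:
    """Count-weighted histogram of anchored coordinates falling inside a region.

    For the 5' terminus, position i counts fragments starting at region.start + i;
    for the 3' terminus, position i counts fragments ending at region.start + i + 1.
    Every sense alignment whose anchored end lies in the region contributes,
    regardless of where its other end falls.
    """
    table = np.zeros(region.length, dtype=np.int64)
    lo, hi = region.start, region.end
    if terminus == FIVE_PRIME:
        for aln in alignments:
            if aln.strand == SENSE and lo <= aln.ref_start < hi:
                table[aln.ref_start - lo] += aln.count
    elif terminus == THREE_PRIME:
        for aln in alignments:
            if aln.strand == SENSE and lo < aln.ref_end <= hi:
                table[aln.ref_end - lo - 1] += aln.count
    else:
        raise ValueError(f"unknown terminus {terminus!r}")
    return table


def end_vs_body_enrichment(
    table: np.ndarray, region: Region, terminus: str, tol: int = 0
) -> EnrichmentResult:
    """One-sided binomial test of boundary counts against the uniform null.

    ``table`` is a per-position anchor-count vector over the region (see
    anchor_table). The boundary window holds 1 + 2*tol positions clipped to the
    region, so a window at a region edge holds 1 + tol.
    """
    g = int(len(table))
    if g < 2:
        raise ValueError(f"degenerate region of {g} position(s)")
    n = int(np.sum(table))
    if n <= 0:
        raise ValueError("no fragments anchored in region; enrichment not computable")
    if terminus == FIVE_PRIME:
        idx = np.arange(0, min(tol + 1, g))
    elif terminus == THREE_PRIME:
        idx = np.arange(max(0, g - 1 - tol), g)
    else:
        raise ValueError(f"unknown terminus {terminus!r}")
    observed = int(np.sum(table[idx]))
    expected_fraction = len(idx) / g
    p_value = float(sps.binom.sf(observed - 1, n, expected_fraction))
    fold = (observed / n) / expected_fraction
    return EnrichmentResult(
        region_name=region.name, terminus=terminus,
        observed_terminal_count=observed, total_region_count=n,
        n_start_positions=g, expected_fraction=expected_fraction,
        fold_enrichment=fold, p_value=p_value,
    )


def enrichment_table(
    alignments: Sequence[AlignmentRecord], ref: AnnotatedReference, tol: int = 0
) -> pd.DataFrame:
    """Enrichment test for every (gene, terminus) pair, BH-corrected q-values.

    Gene ends with no anchored fragments are reported with NaN statistics rather
    than dropped, so the multiplicity of the correction is stable.
    """
    rows = []
    for region in ref.regions:
        if region.role != GENE:
            continue
        for terminus in (FIVE_PRIME, THREE_PRIME):
            table = anchor_table(alignments, region, terminus)
            if table.sum() == 0:
                rows.append(
                    dict(region=region.name, terminus=terminus, observed=0, total=0,
                         n_positions=region.length, expected_fraction=np.nan,
                         fold_enrichment=np.nan, p_value=np.nan)
                )
                continue
            res = end_vs_body_enrichment(table, region, terminus, tol)
            rows.append(
                dict(region=res.region_name, terminus=res.terminus,
                     observed=res.observed_terminal_count, total=res.total_region_count,
                     n_positions=res.n_start_positions,
                     expected_fraction=res.expected_fraction,
                     fold_enrichment=res.fold_enrichment, p_value=res.p_value)
            )
    df = pd.DataFrame(rows)
    df["q_value"] = np.nan
    mask = df["p_value"].notna()
    if mask.any():
        df.loc[mask, "q_value"] = sps.false_discovery_control(
            df.loc[mask, "p_value"].to_numpy(), method="bh"
        )
    return df
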