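"""Descriptive outputs: length distributions, coverage, top sequences, run summary.

All percentages in the summary are stored together with their numerator and
denominator so every number is recomputable from the file alone. Output files are
byte-identical across repeated runs on identical input. TSV/JSON are the contract;
plots are optional artifacts behind a flag.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import percent
from .align import SENSE, AlignmentRecord, MappingStats
from .readio import CollapsedRead, QCStats
from .reference import AnnotatedReference
from .series import RRFSeries


@dataclass
class CoverageProfile:
    counts: np.ndarray  # per-position read count over the sense strand
    excluded_sequences: tuple[str, ...] = ()


def length_distribution(
    collapsed: Sequence[CollapsedRead],
    alignments: Sequence[AlignmentRecord] | None = None,
) -> pd.DataFrame:
    """Duplicate-weighted length histograms for all reads and the aligned (rRNA) subset."""
    all_counts: dict[int, int] = {}
    for cr in collapsed:
        all_counts[len(cr.sequence)] = all_counts.get(len(cr.sequence), 0) + cr.count
    rrna_counts: dict[int, int] = {}
    for aln in alignments or ():
        L = len(aln.read_sequence)
        rrna_counts[L] = rrna_counts.get(L, 0) + aln.count
    lengths = sorted(set(all_counts) | set(rrna_counts))
    return pd.DataFrame(
        {
            "length": lengths,
            "all_count": [all_counts.get(L, 0) for L in lengths],
            "rrna_count": [rrna_counts.get(L, 0) for L in lengths],
        }
    )


def coverage_profile(
    alignments: Iterable[AlignmentRecord],
    ref: AnnotatedReference,
    exclude: Sequence[str] = (),
) -> CoverageProfile:
    """Per-position sense-strand read counts, with exact-sequence exclusion.

    Excluding the handful of extremely duplicated sequences avoids a PCR-duplication
    artifact dominating the profile; matching is exact against the read sequence.
    """
    excluded = tuple(exclude)
    excluded_set = set(excluded)
    counts = np.zeros(len(ref), dtype=np.int64)
    for aln in alignments:
        if aln.strand != SENSE or aln.read_sequence in excluded_set:
            continue
        counts[aln.ref_start : aln.ref_end] += aln.count
    return CoverageProfile(counts=counts, excluded_sequences=excluded)


def top_sequences(
    collapsed: Sequence[CollapsedRead], stats: QCStats, n: int = 10
) -> pd.DataFrame:
    """Top-n sequences by count with their share of cleaned reads (two decimals)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rows = [
        dict(
            sequence=cr.sequence,
            length=len(cr.sequence),
            count=cr.count,
            percent_of_cleaned=percent(cr.count, stats.n_cleaned, 2),
        )
        for cr in sorted(collapsed, key=lambda c: (-c.count, c.sequence))[:n]
    ]
    return pd.DataFrame(rows, columns=["sequence", "length", "count", "percent_of_cleaned"])


@dataclass
class RunSummary:
    qc: QCStats
    mapping: MappingStats
    region_table: pd.DataFrame
    gene_fraction_percent: float | None
    top_sequences: pd.DataFrame
    series: list[RRFSeries]
    enrichment: pd.DataFrame
    parameters: dict = field(default_factory=dict)


def _series_frame(series: Sequence[RRFSeries]) -> pd.DataFrame:
    # human-readable 1-based inclusive boundary position: a 5' anchor is a start
    # (0-based + 1), a 3' anchor is an exclusive end (already the 1-based last base)
    rows = [
        dict(
            region=s.region_name,
            terminus=s.terminus,
            anchor_1based=s.anchor + 1 if s.terminus == "5p" else s.anchor,
            total_count=s.total_count,
            max_ladder_run=s.max_run,
            called=s.called,
            length_counts=",".join(f"{L}:{c}" for L, c in sorted(s.length_histogram.items())),
        )
        for s in series
    ]
    return pd.DataFrame(
        rows,
        columns=["region", "terminus", "anchor_1based", "total_count",
                 "max_ladder_run", "called", "length_counts"],
    )


def summary_dict(summary: RunSummary) -> dict:
    """JSON-ready dictionary; every percentage sits beside its numerator/denominator."""
    qc, mp = summary.qc, summary.mapping
    d = {
        "qc": {
            "n_raw": qc.n_raw,
            "n_cleaned": qc.n_cleaned,
            "q20_percent": qc.q20_percent,
            "length_histogram": {str(k): v for k, v in sorted(qc.length_histogram.items())},
        },
        "mapping": {
            "n_cleaned_reads": mp.n_cleaned_reads,
            "n_aligned_reads": mp.n_aligned_reads,
            "n_sense": mp.n_sense,
            "n_antisense": mp.n_antisense,
            "mapping_rate_percent": (
                percent(mp.n_aligned_reads, mp.n_cleaned_reads, 1)
                if mp.n_cleaned_reads else None
            ),
            "sense_percent": (
                percent(mp.n_sense, mp.n_aligned_reads, 2) if mp.n_aligned_reads else None
            ),
        },
        "gene_fraction_percent": summary.gene_fraction_percent,
        "region_table": summary.region_table.to_dict(orient="records"),
        "top_sequences": summary.top_sequences.to_dict(orient="records"),
        "series": _series_frame(summary.series).to_dict(orient="records"),
        "enrichment": summary.enrichment.to_dict(orient="records"),
        "parameters": summary.parameters,
    }
    return d


def write_summary(
    summary: RunSummary,
    destination: str | Path,
    coverage: CoverageProfile | None = None,
    length_hist: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write summary.json plus the TSV tables; returns the paths written."""
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["summary"] = dest / "summary.json"
    with open(paths["summary"], "w") as fh:
        json.dump(summary_dict(summary), fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")

    paths["regions"] = dest / "regions.tsv"
    summary.region_table.to_csv(paths["regions"], sep="\t", index=False)

    paths["top_seqs"] = dest / "top_seqs.tsv"
    summary.top_sequences.to_csv(paths["top_seqs"], sep="\t", index=False)

    paths["series"] = dest / "series.tsv"
    _series_frame(summary.series).to_csv(paths["series"], sep="\t", index=False)

    paths["enrichment"] = dest / "enrichment.tsv"
    summary.enrichment.to_csv(paths["enrichment"], sep="\t", index=False)

    if length_hist is not None:
        paths["length_hist"] = dest / "length_hist.tsv"
        length_hist.to_csv(paths["length_hist"], sep="\t", index=False)

    if coverage is not None:
        paths["coverage"] = dest / "coverage.tsv"
        cov = pd.DataFrame(
            {"position_1based": np.arange(1, len(coverage.counts) + 1),
             "count": coverage.counts}
        )
        cov.to_csv(paths["coverage"], sep="\t", index=False)

    return paths


def load_summary(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def plot_report(
    destination: str | Path,
    length_hist: pd.DataFrame | None = None,
    coverage: CoverageProfile | None = None,
    ref: AnnotatedReference | None = None,
) -> list[Path]:
    """Optional PNG plots (length histogram, coverage profile with region shading)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    written = []
    if length_hist is not None and len(length_hist):
        fig, ax = plt.subplots(figsize=(7, 4))
        w = 0.4
        ax.bar(length_hist["length"] - w / 2, length_hist["all_count"], w, label="all reads")
        ax.bar(length_hist["length"] + w / 2, length_hist["rrna_count"], w, label="rRNA reads")
        ax.set_xlabel("read length (nt)")
        ax.set_ylabel("read count")
        ax.legend()
        fig.tight_layout()
        p = dest / "length_hist.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        written.append(p)
    if coverage is not None:
        fig, ax = plt.subplots(figsize=(9, 4))
        ax.fill_between(np.arange(1, len(coverage.counts) + 1), coverage.counts, step="mid")
        if ref is not None:
            for r in ref.regions:
                ax.axvspan(r.start + 1, r.end, alpha=0.12,
                           color="tab:orange" if r.role == "gene" else "tab:gray")
                ax.text((r.start + r.end) / 2, ax.get_ylim()[1] * 0.95, r.name,
                        ha="center", va="top", fontsize=8)
        ax.set_xlabel("reference position (1-based)")
        ax.set_ylabel("read count")
        fig.tight_layout()
        p = dest / "coverage.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        written.append(p)
    return written
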