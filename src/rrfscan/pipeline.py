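"""End-to-end orchestration: clean -> align (or import SAM) -> classify -> series -> report.

Every output is stamped with the full parameter set; per-stage read-count
conservation is logged so silent read loss is detectable. Re-running on identical
inputs overwrites with byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import align as _align
from . import classify as _classify
from . import readio as _readio
from . import report as _report
from . import series as _series
from .reference import AnnotatedReference, load_reference

log = logging.getLogger("rrfscan")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    reads: str | Path | None = None
    reference: str | Path | None = None
    regions: str | Path | None = None
    outdir: str | Path = "rrfscan_out"
    sam: str | Path | None = None  # import external alignments instead of aligning
    adapter: str | None = None
    min_len: int = 15
    seed_k: int = 7
    end_tolerance: int = 0
    min_count: int = 1
    min_run: int = 3
    min_total: int = 10
    exclude: tuple[str, ...] = ()
    keep_antisense: bool = True
    top_n: int = 10
    make_plots: bool = False
    write_alignments: bool = False
    log_level: str = "INFO"
    extra: dict = field(default_factory=dict)

    def parameter_dict(self) -> dict:
        return {
            "reads": str(self.reads) if self.reads else None,
            "reference": str(self.reference) if self.reference else None,
            "regions": str(self.regions) if self.regions else None,
            "sam": str(self.sam) if self.sam else None,
            "adapter": self.adapter,
            "min_len": self.min_len,
            "max_edits": 1,  # fixed by the alignment contract
            "seed_k": self.seed_k,
            "end_tolerance": self.end_tolerance,
            "min_count": self.min_count,
            "min_run": self.min_run,
            "min_total": self.min_total,
            "exclude": list(self.exclude),
            "keep_antisense": self.keep_antisense,
            "top_n": self.top_n,
        }


def _check_inputs(cfg: PipelineConfig) -> None:
    for label, p in (("reads", cfg.reads), ("reference", cfg.reference),
                     ("regions", cfg.regions), ("sam", cfg.sam)):
        if p is not None and not Path(p).exists():
            raise PipelineError("inputs", f"{label} file not found: {p}")
    if cfg.reads is None and cfg.sam is None:
        raise PipelineError("inputs", "either reads or a SAM file is required")
    if cfg.reference is None or cfg.regions is None:
        raise PipelineError("inputs", "reference FASTA and region annotation are required")


def run_pipeline(
    cfg: PipelineConfig, reference: AnnotatedReference | None = None
) -> _report.RunSummary:
    logging.basicConfig(level=cfg.log_level)
    if reference is None:
        _check_inputs(cfg)
        try:
            reference = load_reference(cfg.reference, cfg.regions)
        except Exception as exc:
            raise PipelineError("reference", str(exc)) from exc
    log.info("reference %s: %d nt, %d regions", reference.id, len(reference),
             len(reference.regions))

    # clean
    try:
        if cfg.reads is not None:
            raw = _readio.read_sequences(cfg.reads)
            cleaned, qc = _readio.clean_reads(raw, adapter=cfg.adapter, min_len=cfg.min_len)
        else:
            cleaned, qc = [], _readio.QCStats()
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("clean", str(exc)) from exc
    log.info("clean: %d raw -> %d cleaned", qc.n_raw, qc.n_cleaned)

    collapsed = _readio.collapse_reads(cleaned)
    if sum(c.count for c in collapsed) != qc.n_cleaned:
        raise PipelineError("collapse", "read-count conservation violated")

    # align or import
    try:
        if cfg.sam is not None:
            alignments, mapping, n_discarded = _align.import_sam(cfg.sam, reference)
            log.info("import_sam: %d aligned, %d discarded by the <=1-edit filter",
                     mapping.n_aligned_reads, n_discarded)
            if cfg.reads is not None:
                mapping.n_cleaned_reads = qc.n_cleaned
        else:
            alignments, mapping = _align.align_all(
                collapsed, reference, k=cfg.seed_k, keep_antisense=cfg.keep_antisense
            )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("align", str(exc)) from exc
    log.info("align: %d/%d reads mapped (%d sense / %d antisense)",
             mapping.n_aligned_reads, mapping.n_cleaned_reads,
             mapping.n_sense, mapping.n_antisense)

    # classify
    pairs = _classify.classify_all(alignments, reference, tol=cfg.end_tolerance)
    region_table, gene_fraction = _classify.region_counts(pairs, reference)
    if int(region_table["count"].sum()) != mapping.n_aligned_reads:
        raise PipelineError("classify", "count partition violated")

    # series + enrichment
    series = _series.group_by_anchor(pairs, reference, min_count=cfg.min_count)
    series = _series.call_series(series, min_run=cfg.min_run, min_total=cfg.min_total)
    enrichment = _series.enrichment_table(alignments, reference, tol=cfg.end_tolerance)

    # report
    top = _report.top_sequences(collapsed, qc, n=cfg.top_n)
    length_hist = _report.length_distribution(collapsed, alignments)
    coverage = _report.coverage_profile(alignments, reference, exclude=cfg.exclude)
    summary = _report.RunSummary(
        qc=qc, mapping=mapping, region_table=region_table,
        gene_fraction_percent=gene_fraction, top_sequences=top,
        series=series, enrichment=enrichment, parameters=cfg.parameter_dict(),
    )
    outdir = Path(cfg.outdir)
    paths = _report.write_summary(summary, outdir, coverage=coverage, length_hist=length_hist)
    if cfg.write_alignments:
        _align.write_sam(alignments, reference, outdir / "alignments.sam")
    if cfg.make_plots:
        _report.plot_report(outdir, length_hist=length_hist, coverage=coverage, ref=reference)
    log.info("report: wrote %d files to %s", len(paths), outdir)
    return summary
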