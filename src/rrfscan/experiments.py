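"""Reusable in-silico experiments over the pipeline.

These drivers back the numbered analysis scripts, the test suite and the acceptance
script, so every reported number comes from one code path. Each takes an explicit
seed and problem size; defaults are the study conditions the synthetic generator
encodes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._util import percent, reverse_complement
from . import align as _align
from . import classify as _classify
from . import readio as _readio
from . import report as _report
from . import series as _series
from .reference import AnnotatedReference
from .simulate import (
    LadderSpec,
    SyntheticConfig,
    make_toy_reference,
    simulate_library,
    truth_compare,
)
from .series import FIVE_PRIME, THREE_PRIME

#: Headline read-count accounting of the tick total-RNA sRNA-seq library
#: (NCBI SRA SRP084097, two pooled adult females; printed counts used as inputs).
TICK_LIBRARY_COUNTS = {
    "n_raw": 13_723_268,
    "n_cleaned": 12_134_881,
    "n_aligned": 3_688_594,
    "n_sense": 3_687_679,
    "top_sequences": [
        ("TATTGAGGCTTAGCCTCTGACTGGAAGGTTTGT", 1_423_580),  # 33-nt 28S rRF3
        ("GAGGCTTAGCCTCTGACTGGAAGGTTTGT", 390_952),  # 29-nt 28S rRF3
        ("TCCGGCGTGGTCTAGTGGCTAGGATATCTGGCT", 288_062),  # 33-nt non-rDNA sRNA
    ],
}


def headline_percentages(counts: dict | None = None) -> dict[str, float]:
    """Recompute the library's headline ratios through the report formulas."""
    c = TICK_LIBRARY_COUNTS if counts is None else counts
    stats = _align.MappingStats(
        n_cleaned_reads=c["n_cleaned"], n_aligned_reads=c["n_aligned"],
        n_sense=c["n_sense"], n_antisense=c["n_aligned"] - c["n_sense"],
    )
    out = {
        "mapping_rate_percent": percent(stats.n_aligned_reads, stats.n_cleaned_reads, 1),
        "sense_strand_percent": _align.strand_fraction(stats),
    }
    qc = _readio.QCStats(n_raw=c["n_raw"], n_cleaned=c["n_cleaned"])
    collapsed = [_readio.CollapsedRead(seq, n) for seq, n in c["top_sequences"]]
    top = _report.top_sequences(collapsed, qc, n=len(collapsed))
    for i, share in enumerate(top["percent_of_cleaned"], 1):
        out[f"top{i}_share_percent"] = float(share)
    return out


# ---------------------------------------------------------------------------
# aligner vs independent brute-force oracle


def _edlib_best(seq: str, ref: str) -> int | None:
    """Best infix edit distance (<=1) of the read on either strand, via edlib."""
    import edlib

    best = None
    for q in (seq, reverse_complement(seq)):
        d = edlib.align(q, ref, mode="HW", task="distance", k=1)["editDistance"]
        if d >= 0 and (best is None or d < best):
            best = d
    return best


def aligner_oracle_check(n_cases: int = 200, seed: int = 0) -> dict:
    """Randomized equivalence check of the seed-and-extend aligner.

    Each case draws a random reference (<=2 kb) and a batch of reads: planted exact
    copies, 1-substitution, 1-nt-gap and 2-substitution variants (on either strand)
    plus a fully random read. Mapped/unmapped status and edit cost are compared with
    an exhaustive banded edit-distance scan (edlib, infix mode, band 1).
    """
    rng = np.random.default_rng(seed)
    n_reads = 0
    n_agree = 0
    for _ in range(n_cases):
        ref_len = int(rng.integers(300, 2001))
        ref = "".join(rng.choice(list("ACGT"), size=ref_len))
        index = _align.SeedIndex(
            AnnotatedReference(id="r", sequence=ref, regions=()), k=7
        )
        reads = []
        L = int(rng.integers(15, 41))
        s = int(rng.integers(0, ref_len - L + 1))
        frag = ref[s : s + L]
        reads.append(frag)  # 0 edits
        reads.append(_substitute(frag, 1, rng))  # 1 mismatch
        reads.append(_gap(frag, rng))  # 1-nt gap
        reads.append(_substitute(frag, 2, rng))  # 2 edits (usually unmapped)
        reads.append("".join(rng.choice(list("ACGT"), size=L)))  # random
        if rng.random() < 0.5:
            reads = [reverse_complement(r) for r in reads]
        for read in reads:
            if len(read) < 15:
                continue
            n_reads += 1
            rec = _align.align_read(read, index)
            mine = None if rec is None else rec.n_mismatch + rec.n_gap
            oracle = _edlib_best(read, ref)
            if mine == oracle:
                n_agree += 1
    return {"n_cases": n_cases, "n_reads": n_reads, "n_agree": n_agree,
            "agreement_fraction": n_agree / n_reads}


def _substitute(seq: str, k: int, rng: np.random.Generator) -> str:
    pos = rng.choice(len(seq), size=min(k, len(seq)), replace=False)
    s = list(seq)
    for p in pos:
        s[p] = "ACGT".replace(s[p], "")[rng.integers(0, 3)]
    return "".join(s)


def _gap(seq: str, rng: np.random.Generator) -> str:
    p = int(rng.integers(1, len(seq) - 1))
    if rng.random() < 0.5:
        return seq[:p] + seq[p + 1 :]  # deletion
    return seq[:p] + "ACGT"[rng.integers(0, 4)] + seq[p:]  # insertion


# ---------------------------------------------------------------------------
# library-level experiments


def ladder_config(seed: int, background: int = 360) -> SyntheticConfig:
    """Four planted ladders (both termini of 5.8S and 28S), 9 lengths at mean depth
    100, background at 10% of the expected planted counts."""
    ladders = tuple(
        LadderSpec(region, terminus, 25, 33, 100.0)
        for region in ("5.8S", "28S")
        for terminus in (FIVE_PRIME, THREE_PRIME)
    )
    return SyntheticConfig(ladders=ladders, n_background=background, seed=seed)


def run_series_detection(cfg: SyntheticConfig, min_run: int = 3, min_total: int = 10,
                         min_count: int = 1):
    """simulate -> clean -> collapse -> align -> classify -> series, returning
    (called series, truth table, reference, alignments, mapping stats)."""
    reads, truth, ref = simulate_library(cfg)
    cleaned, _qc = _readio.clean_reads(reads, min_len=15)
    collapsed = _readio.collapse_reads(cleaned)
    alignments, stats = _align.align_all(collapsed, ref)
    pairs = _classify.classify_all(alignments, ref, tol=0)
    series = _series.group_by_anchor(pairs, ref, min_count=min_count)
    series = _series.call_series(series, min_run=min_run, min_total=min_total)
    return series, truth, ref, alignments, stats


def ladder_recovery(n_seeds: int = 20, seed0: int = 0) -> dict:
    """Precision/recall of called series and anchor exactness over seeded replicates."""
    n_exact = n_tp = n_called = n_eligible = 0
    per_seed = []
    for i in range(n_seeds):
        cfg = ladder_config(seed=seed0 + i)
        series, truth, ref, _, _ = run_series_detection(cfg)
        rep = truth_compare(truth, series, ref)
        per_seed.append(rep)
        n_called += rep["n_called"]
        n_eligible += rep["n_planted_eligible"]
        n_tp += round(rep["precision"] * rep["n_called"])
        n_exact += sum(1 for r in rep["per_ladder"] if r["anchor_recovered"])
    return {
        "n_seeds": n_seeds,
        "precision": n_tp / n_called if n_called else 1.0,
        "recall": n_tp / n_eligible if n_eligible else 1.0,
        "anchors_exact_fraction": n_exact / n_eligible if n_eligible else 1.0,
        "per_seed": per_seed,
    }


def null_calibration(
    n_libraries: int = 167,
    n_background: int = 10_000,
    n_zero_call_libraries: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Calibration of the enrichment test and series caller on pure background.

    Simulates libraries with no planted ladders, runs the full pipeline on each, and
    pools the per-(gene, terminus) binomial p-values; also counts libraries (among
    the first n_zero_call_libraries) in which any series is called at defaults.
    """
    ref = make_toy_reference(seed=seed)
    index = _align.SeedIndex(ref, k=7)
    p_values: list[float] = []
    zero_call = 0
    n_zero_checked = 0
    for i in range(n_libraries):
        cfg = SyntheticConfig(reference=ref, ladders=(), n_background=n_background,
                              seed=seed + 1 + i)
        reads, _truth, _ = simulate_library(cfg)
        cleaned, _qc = _readio.clean_reads(reads, min_len=15)
        collapsed = _readio.collapse_reads(cleaned)
        alignments, _stats = _align.align_all(collapsed, ref, index=index)
        for region in ref.genes:
            for terminus in (FIVE_PRIME, THREE_PRIME):
                table = _series.anchor_table(alignments, region, terminus)
                if table.sum() == 0:
                    continue
                res = _series.end_vs_body_enrichment(table, region, terminus, tol=0)
                p_values.append(res.p_value)
        if i < n_zero_call_libraries:
            n_zero_checked += 1
            pairs = _classify.classify_all(alignments, ref, tol=0)
            series = _series.group_by_anchor(pairs, ref)
            series = _series.call_series(series)
            if not any(s.called for s in series):
                zero_call += 1
    pv = np.asarray(p_values)
    return {
        "n_tests": int(pv.size),
        "rejection_rate_alpha05": float(np.mean(pv < alpha)),
        "fraction_p_below_01": float(np.mean(pv < 0.01)),
        "n_zero_call_libraries": n_zero_checked,
        "zero_call_fraction": zero_call / n_zero_checked if n_zero_checked else 1.0,
        "p_values": pv,
    }


def study_like_config(seed: int = 0) -> SyntheticConfig:
    """A desk-scale library shaped like the tick run: rRF ladders on both termini of
    5.8S and 28S (rRF3 deeper than rRF5), none on 18S, uniform background, and heavy
    PCR duplication of the two most abundant 28S rRF3 sequences."""
    ladders = (
        LadderSpec("5.8S", FIVE_PRIME, 20, 31, 40.0),
        LadderSpec("5.8S", THREE_PRIME, 22, 35, 160.0),
        LadderSpec("28S", FIVE_PRIME, 20, 31, 70.0),
        LadderSpec("28S", THREE_PRIME, 20, 36, 320.0),
    )
    return SyntheticConfig(
        ladders=ladders,
        n_background=2000,
        dup_sequences=((f"28S:{THREE_PRIME}:33", 1200), (f"28S:{THREE_PRIME}:29", 400)),
        seed=seed,
    )
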