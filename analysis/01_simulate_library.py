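#!/usr/bin/env python
"""Simulate the study-like sRNA-seq library and write it to results/sim/.

The library plants terminus-anchored 1-bp ladders on both ends of the 5.8S and
28S genes (the 3' ladders deeper than the 5' ones), none on 18S, a uniform
degradation background, and heavy PCR duplication of the two most abundant 28S
rRF3 sequences - the structure the degradation-null analysis is designed to
resolve. Ground truth is written alongside the reads.
"""

from pathlib import Path

from rrfscan.experiments import study_like_config
from rrfscan.reference import write_bed
from rrfscan.simulate import simulate_library, write_fastq, write_truth

OUT = Path("results/sim")


def main(seed: int = 0) -> None:
    cfg = study_like_config(seed=seed)
    reads, truth, ref = simulate_library(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    write_fastq(reads, OUT / "reads.fastq")
    write_truth(truth, OUT / "truth.tsv")
    with open(OUT / "reference.fasta", "w") as fh:
        fh.write(f">{ref.id}\n{ref.sequence}\n")
    write_bed(ref, OUT / "reference.bed")
    n_ladder = int((truth["origin"] == "ladder").sum())
    n_dup = int((truth["origin"] == "duplicate").sum())
    n_bg = int((truth["origin"] == "background").sum())
    print(f"wrote {len(reads)} reads to {OUT}/")
    print(f"  planted ladder reads: {n_ladder}")
    print(f"  PCR-duplicate reads:  {n_dup}")
    print(f"  background reads:     {n_bg}")
    print(f"  reference: {ref.id}, {len(ref)} nt, "
          f"regions {[r.name for r in ref.regions]}")


if __name__ == "__main__":
    main()
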