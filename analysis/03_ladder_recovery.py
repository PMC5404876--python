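#!/usr/bin/env python
"""Planted-ladder recovery experiment: can the pipeline find what was planted?

Twenty seeded replicates of a library with four planted ladders (both termini of
5.8S and 28S, nine consecutive lengths at mean depth 100) over a background at
10% of the planted counts. Reports precision/recall of called series, anchor
exactness, and per-ladder count recall; writes results/ladder_recovery.tsv.
"""

from pathlib import Path

import pandas as pd

from rrfscan.experiments import ladder_recovery

OUT = Path("results")


def main(n_seeds: int = 20, seed0: int = 0) -> None:
    result = ladder_recovery(n_seeds=n_seeds, seed0=seed0)
    rows = []
    for i, rep in enumerate(result["per_seed"]):
        for ladder in rep["per_ladder"]:
            rows.append({"seed": seed0 + i, **ladder})
    df = pd.DataFrame(rows)
    OUT.mkdir(parents=True, exist_ok=True)
    df.to_csv(OUT / "ladder_recovery.tsv", sep="\t", index=False)
    print(f"{n_seeds} replicates, 4 planted ladders each:")
    print(f"  precision of called series: {result['precision']:.3f}")
    print(f"  recall of planted ladders:  {result['recall']:.3f}")
    print(f"  anchors recovered exactly:  {result['anchors_exact_fraction']:.3f}")
    print(f"  median count recall: {df['count_recall'].median():.4f}")
    print(f"per-ladder table written to {OUT / 'ladder_recovery.tsv'}")


if __name__ == "__main__":
    main()
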