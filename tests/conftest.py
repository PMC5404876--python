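from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rrfscan.simulate import make_toy_reference

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy_ref():
    """Default toy rDNA reference (18S-ITS1-5.8S-ITS2-28S, 3950 nt)."""
    return make_toy_reference(seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def write_fasta(path, records):
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")
    return path


def write_fastq(path, records):
    """records: (id, seq, qual) triples."""
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
    return path
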