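"""Shared fixtures: a cached default simulation and small hand-built inputs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ricecerna.annotation_io import ExpressionMatrix, GenomicInterval, TranscriptRecord
from ricecerna.synthetic import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def sim_dataset():
    """Default-parameter simulated dataset (seed 0), shared across tests."""
    return simulate_dataset(SimConfig(seed=0))


@pytest.fixture()
def small_counts():
    """2 features x 4 samples count matrix with easy hand arithmetic."""
    df = pd.DataFrame(
        {
            "CK1": [100.0, 10.0],
            "CK2": [110.0, 20.0],
            "D1": [400.0, 40.0],
            "D2": [440.0, 50.0],
        },
        index=["featA", "featB"],
    )
    cond = {"CK1": "CK", "CK2": "CK", "D1": "D", "D2": "D"}
    return ExpressionMatrix(df, "count", cond)


def make_transcript(
    tid="T1",
    chrom="chr1",
    exon_spans=((101, 300), (401, 600)),
    strand="+",
    class_code="u",
    sequence=None,
    biotype="lncRNA_candidate",
):
    exons = [GenomicInterval(chrom, a, b, strand) for a, b in exon_spans]
    locus = GenomicInterval(
        chrom, min(e.start for e in exons), max(e.end for e in exons), strand
    )
    return TranscriptRecord(tid, f"gene_{tid}", locus, exons, class_code,
                            sequence, biotype)


@pytest.fixture()
def transcript_factory():
    return make_transcript


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


@pytest.fixture()
def seq_factory():
    return random_seq
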