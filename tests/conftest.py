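"""Shared fixtures: everything is generated programmatically and seeded."""

from __future__ import annotations

import numpy as np
import pytest

from exolm import simdata
from exolm.core import AlignedRead, ReferenceGenome
from exolm.tokenizer import build_vocab


@pytest.fixture(scope="session")
def vocab():
    return build_vocab()


@pytest.fixture(scope="session")
def tiny_ref():
    """2-kb single-contig reference, fixed seed."""
    cfg = simdata.SimConfig(n_contigs=1, contig_length=2000, seed=11)
    return simdata.simulate_reference(cfg)


@pytest.fixture(scope="session")
def small_cohort(tiny_ref):
    """Two subjects with shallow coverage over the 2-kb reference."""
    cfg = simdata.SimConfig(
        n_contigs=1,
        contig_length=2000,
        coverage_min=2,
        coverage_max=5,
        variant_rate=5e-3,
        n_subjects=2,
        seed=11,
    )
    return simdata.simulate_cohort(tiny_ref, cfg)


@pytest.fixture(scope="session")
def small_reads(small_cohort):
    return [r for _, reads, _ in small_cohort for r in reads]


def make_read(contig, start, bases, quality=30, read_id=None, subject="S0"):
    return AlignedRead(
        read_id=read_id or f"{subject}:{contig}:{start}",
        contig=contig,
        start=start,
        bases=bases,
        qualities=tuple([quality] * len(bases)),
        subject_id=subject,
    )


@pytest.fixture
def toy_ref():
    """Deterministic 400-bp toy contig for hand-checkable fixtures."""
    rng = np.random.default_rng(5)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=400))
    return ReferenceGenome([("toy", seq)])
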