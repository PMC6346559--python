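"""Shared fixtures: random sequence helpers and cached simulator bundles."""

from __future__ import annotations

import numpy as np
import pytest

from screenaudit.alignment import Genome
from screenaudit.simulate import make_fixture

BASES = np.array(list("ACGT"))


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, n))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def sox_bundle():
    return make_fixture("sox9_sox10_like", seed=11)


@pytest.fixture(scope="session")
def snp_bundle():
    return make_fixture("snp_pam_like", seed=3)


@pytest.fixture(scope="session")
def myl12_bundle():
    return make_fixture("myl12_like", seed=5)


@pytest.fixture(scope="session")
def readthrough_bundle():
    return make_fixture("tmed7_ticam2_like", seed=5)


@pytest.fixture(scope="session")
def double_mm_bundle():
    return make_fixture("double_mm_like", seed=5)


@pytest.fixture
def table1_genome(rng) -> tuple[Genome, dict[str, str]]:
    """Mini-genome embedding the SOX9/SOX10 protospacer pair with AGG PAMs."""
    spacers = {
        "A3": "GCACCTGGCTGACCGCCTCG",  # SOX9 protospacer
        "B3": "GCACCTGGCTGACGGCCTCG",  # SOX10 protospacer
        "B4": "GCTGGTACTTGTAGTCCGGG",  # SOX10 protospacer (guide B4)
        "SOX8": "GCTGGTACTTGTAGTCGGGG",  # SOX8-variant protospacer for B4
    }
    genome = Genome(
        {
            "chr17": random_seq(rng, 120) + spacers["A3"] + "AGG" + random_seq(rng, 80),
            "chr22": random_seq(rng, 60) + spacers["B3"] + "AGG" + random_seq(rng, 60),
        }
    )
    return genome, spacers
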