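from __future__ import annotations

import numpy as np
import pytest

from victoriscan import annotate, build_frame_index, generate_genome, scan_all
from victoriscan.genome_io import GenomeRecord

BASES = np.array(list("ACGU"))


@pytest.fixture(scope="session")
def paper_genome():
    """The paper-layout synthetic genome and its truth layout (seed 42)."""
    return generate_genome("paper_layout", seed=42)


@pytest.fixture(scope="session")
def paper_record(paper_genome):
    return paper_genome[0]


@pytest.fixture(scope="session")
def paper_truth(paper_genome):
    return paper_genome[1]


@pytest.fixture(scope="session")
def paper_layout(paper_record):
    return annotate(paper_record)


@pytest.fixture(scope="session")
def paper_signals(paper_record, paper_layout):
    return scan_all(paper_record, paper_layout)


@pytest.fixture(scope="session")
def paper_index(paper_record):
    return build_frame_index(paper_record)


def random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(20240615)


@pytest.fixture
def random_record(rng):
    def make(length: int, seed: int | None = None) -> GenomeRecord:
        r = np.random.default_rng(seed) if seed is not None else rng
        return GenomeRecord(id=f"rand{length}", sequence=random_rna(r, length))

    return make
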