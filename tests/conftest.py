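import random

import pytest

from methcap.io_formats import CpGRecord, SequenceRecord, TargetRegion
from methcap.io_formats import percent_methylation


def random_dna(rng: random.Random, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(alphabet) for _ in range(length))


def make_cov_record(rng: random.Random, chrom: str = "chr1",
                    pos: int | None = None) -> CpGRecord:
    pos = pos if pos is not None else rng.randrange(1, 10000)
    m = rng.randrange(0, 30)
    u = rng.randrange(0, 30)
    return CpGRecord(chrom, pos, percent_methylation(m, u), m, u)


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20240901)


@pytest.fixture
def toy_genome() -> list[SequenceRecord]:
    return [
        SequenceRecord("chr1", "AAACGTTTACGTACGGGCATTTACGCGTAAAC"),
        SequenceRecord("chr2", "ACGT" * 25),
    ]


@pytest.fixture
def toy_region() -> TargetRegion:
    return TargetRegion("chr1", 2, 6, "toy", "+")
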