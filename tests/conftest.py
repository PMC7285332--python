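import numpy as np
import pytest

from circex.seqio import SequenceRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_dna(rng, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


@pytest.fixture
def random_record(rng):
    def make(n: int, id: str = "r") -> SequenceRecord:
        return SequenceRecord(id=id, sequence=random_dna(rng, n))

    return make
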