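import numpy as np
import pytest

from gallsift.seqio import SequenceRecord


def random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    at = (1.0 - gc) / 2.0
    codes = rng.choice(4, size=length, p=[at, gc / 2, gc / 2, at])
    return "".join("ACGT"[c] for c in codes)


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture(scope="session")
def small_genome():
    """One 10-kb N-free chromosome used by mapper and aligner tests."""
    g = np.random.default_rng(777)
    return [SequenceRecord("chrA", random_seq(g, 10_000))]
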