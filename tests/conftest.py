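import numpy as np
import pytest

from ampliconkit.seqio import Sequence


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_dna(rng, length):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, length))


@pytest.fixture
def make_dna(rng):
    def _make(length):
        return random_dna(rng, length)
    return _make


@pytest.fixture
def make_seq(rng):
    counter = {"n": 0}

    def _make(length, with_quals=False):
        counter["n"] += 1
        quals = [int(q) for q in rng.integers(2, 42, length)] if with_quals else None
        return Sequence(f"seq{counter['n']}", random_dna(rng, length), qualities=quals)
    return _make
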