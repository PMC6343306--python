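import numpy as np
import pytest

from pybsmeth import (
    ReferenceGenome,
    build_index,
    convert_genome,
)
from pybsmeth.aligner import AlignParams, Read


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def random_genome():
    """A 20 kb random genome shared across alignment tests."""
    from pybsmeth.simulator import simulate_genome

    return simulate_genome(20_000, gc_fraction=0.42, seed=7)


@pytest.fixture(scope="session")
def indexed_genome(random_genome):
    pair = convert_genome(random_genome)
    return pair, build_index(pair, seed_len=12)


@pytest.fixture
def params():
    return AlignParams()


def make_read(seq: str, rid: str = "r", q: int = 30) -> Read:
    return Read(rid, seq, [q] * len(seq))


@pytest.fixture
def read_factory():
    return make_read
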