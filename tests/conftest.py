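import numpy as np
import pytest

from genecat import LabeledSequence, make_divergence_chain

BASES = "ACGT"


def random_seq(length: int, seed: int, sid: str = "s", **labels) -> LabeledSequence:
    rng = np.random.default_rng(seed)
    return LabeledSequence(id=sid, bases="".join(rng.choice(list(BASES), size=length)),
                           **labels)


def hamming(a: str, b: str) -> int:
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b))


@pytest.fixture(scope="session")
def chain4():
    """Length-1000 chain with four 5% steps on disjoint sites."""
    return make_divergence_chain(1000, [0.05] * 4, seed=7)


@pytest.fixture(scope="session")
def short_chain():
    """Small chain for oracle-aligner comparisons (cheap to align exactly)."""
    return make_divergence_chain(150, [0.05, 0.05, 0.10], seed=3)
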