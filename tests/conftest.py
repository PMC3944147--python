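import numpy as np
import pytest

from hashalign.refindex import AlignerConfig, ReferenceSet, ScoringScheme


def random_seq(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_cfg():
    """Config suited to toy references: short seeds, permissive act."""
    return AlignerConfig(hs=11, act=20)


@pytest.fixture
def scoring():
    return ScoringScheme()


@pytest.fixture
def toy_refset(rng):
    """5 kb random reference, single sequence."""
    return ReferenceSet.from_sequences([("chr1", random_seq(rng, 5000))])
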