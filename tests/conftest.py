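import numpy as np
import pytest

from lphist.sequence_io import generate_random_sequence


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def iid_corpus(rng):
    """31 random i.i.d. sequences, mirroring a genome-panel-sized corpus."""
    return [
        generate_random_sequence(400, "iid", rng, id=f"sp{k:02d}")
        for k in range(31)
    ]


@pytest.fixture
def three_sequences(rng):
    return [
        generate_random_sequence(300, "iid", rng, id=f"s{k}") for k in range(3)
    ]
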