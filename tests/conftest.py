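import numpy as np
import pytest

from dfp import MACCS166, BitMatrix, generate_random_reference


@pytest.fixture(scope="session")
def random_reference():
    """The standard random reference: 1500 x 166 Bernoulli(0.5), seeded."""
    return generate_random_reference(n=1500, scheme=MACCS166, p=0.5, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_matrix(bits, label="test", ids=None):
    """Build a BitMatrix from a nested list / array, inferring the scheme."""
    from dfp import scheme_for_length

    bits = np.asarray(bits, dtype=np.uint8)
    n, length = bits.shape
    if ids is None:
        ids = [f"m{i}" for i in range(1, n + 1)]
    return BitMatrix(ids=ids, bits=bits,
                     scheme=scheme_for_length(length), source_label=label)
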