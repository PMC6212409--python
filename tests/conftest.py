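import numpy as np
import pytest

from ginsentides import data

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def tp1() -> str:
    return data.TP1


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_sequences(rng, n, min_len=5, max_len=40, alphabet=AMINO_ACIDS):
    letters = list(alphabet)
    for _ in range(n):
        length = int(rng.integers(min_len, max_len + 1))
        yield "".join(rng.choice(letters, size=length))
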