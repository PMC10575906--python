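import numpy as np
import pytest

from esfuse import ContingencyTable


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def random_table(rng):
    """Factory of random non-degenerate tables of a given shape."""

    def make(r=2, c=2, n=500):
        while True:
            probs = rng.dirichlet(np.ones(r * c))
            counts = rng.multinomial(n, probs).reshape(r, c)
            table = ContingencyTable(counts)
            if not table.is_degenerate():
                return table

    return make
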