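import numpy as np
import pytest

from bitclose import BitTable, MiningConfig


@pytest.fixture
def toy4() -> BitTable:
    """Four transactions over items A,B,C: 111 / 110 / 101 / 011."""
    return BitTable.from_dense(
        [[1, 1, 1], [1, 1, 0], [1, 0, 1], [0, 1, 1]], item_labels=list("ABC")
    )


@pytest.fixture
def toy3() -> BitTable:
    """Three transactions: AB / AB / ABC — A and B are absorbed by AB."""
    return BitTable.from_dense(
        [[1, 1, 0], [1, 1, 0], [1, 1, 1]], item_labels=list("ABC")
    )


def random_instance(seed: int):
    """One small seeded instance in the regime the equivalence suite covers."""
    rng = np.random.default_rng(seed)
    n_rows = int(rng.integers(5, 26))
    n_cols = int(rng.integers(4, 16))
    density = float(rng.uniform(0.05, 0.6))
    minsupp = int(rng.integers(1, 6))
    vals = (rng.random((n_rows, n_cols)) < density).astype(np.int8)
    return BitTable.from_dense(vals), MiningConfig(minsupp=minsupp)
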