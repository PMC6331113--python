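import numpy as np
import pytest


def random_confusion(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random non-negative matrix with S > 0: mixed zeros and smooth entries."""
    a = rng.gamma(shape=0.6, scale=10.0, size=(n, n))
    a[rng.random((n, n)) < 0.25] = 0.0
    if a.sum() == 0:
        a[rng.integers(n), rng.integers(n)] = 1.0
    return a


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
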