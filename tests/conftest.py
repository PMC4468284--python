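import numpy as np
import pytest

from mrrmrr import DataMatrix, GeneratorSpec, generate

#: Seed of the planted desk-scale benchmark used across the suite.
BENCHMARK_SEED = 12345


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture
def small_data(rng):
    """30 samples x 8 variables, two planted signals (columns 0 and 3)."""
    n = 30
    Y = np.repeat([1, 2], n // 2)
    X = rng.normal(size=(n, 8))
    X[Y == 2, 0] += 2.0
    X[Y == 2, 3] += 1.5
    return DataMatrix(X=X, Y=Y)


@pytest.fixture(scope="session")
def benchmark_data():
    """The fixed planted benchmark: 24+24 samples, p=500, 10 informative."""
    return generate(GeneratorSpec(seed=BENCHMARK_SEED))
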