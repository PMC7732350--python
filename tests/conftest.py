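import numpy as np
import pytest

from leakfree import default_benchmark


@pytest.fixture(scope="session")
def benchmark():
    """Nominal benchmark forward model (normalized, 11 electrodes x 21 sources)."""
    return default_benchmark()


@pytest.fixture(scope="session")
def benchmark_raw():
    """Same geometry without the unit-spectral-norm normalization."""
    return default_benchmark(normalize=False)


@pytest.fixture(scope="session")
def true_pair(benchmark):
    """Grid indices of the active sources at -1 mm and +1 mm."""
    return (benchmark.source_index(-1.0), benchmark.source_index(1.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
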