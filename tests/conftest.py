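import numpy as np
import pytest

from irbfnn import SimulationSpec, simulate_ee_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def ee_dataset():
    """Protocol-scale synthetic HR/MI/EE dataset (252 pairs)."""
    return simulate_ee_dataset(SimulationSpec(n=252, seed=42))


@pytest.fixture(scope="session")
def small_clouds():
    """Twenty small random datasets (N <= 50, d <= 3) for clustering checks."""
    out = []
    for s in range(20):
        r = np.random.default_rng(1000 + s)
        n = int(r.integers(10, 51))
        d = int(r.integers(1, 4))
        out.append(r.normal(size=(n, d)))
    return out
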