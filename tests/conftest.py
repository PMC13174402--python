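import numpy as np
import pytest

from cedr import build_scenario, generate_dataset


@pytest.fixture(scope="session")
def simdata3_low():
    """One SimData3 low-noise dataset (easiest benchmark cell)."""
    return generate_dataset(build_scenario("SimData3", "low"), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def two_gaussians():
    """Two well-separated spherical Gaussians in 2-d with labels."""
    rng = np.random.default_rng(3)
    n = 100
    X = np.vstack([rng.normal(-5.0, 1.0, size=(n, 2)),
                   rng.normal(5.0, 1.0, size=(n, 2))])
    labels = np.repeat([1, 2], n)
    return X, labels
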