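import numpy as np
import pytest

from relicred import (AnalysisConfig, ItemResponseMatrix, McmcConfig,
                      load_example)


@pytest.fixture(scope="session")
def sigma2():
    """2 items, unit variances, correlation .5."""
    return np.array([[1.0, 0.5], [0.5, 1.0]])


@pytest.fixture(scope="session")
def sigma3():
    """3 items, unit variances, all covariances .5."""
    s = np.full((3, 3), 0.5)
    np.fill_diagonal(s, 1.0)
    return s


@pytest.fixture(scope="session")
def example_data():
    """The bundled 78 x 5 mania-scale dataset."""
    return load_example()


@pytest.fixture
def small_mcmc():
    """Light chain layout for unit tests."""
    return McmcConfig(chains=2, iterations=200, burn_in=20, thin=1)


@pytest.fixture
def tiny_data():
    rng = np.random.default_rng(7)
    f = rng.normal(size=60)
    vals = np.outer(f, [0.7, 0.7, 0.7]) + rng.normal(0, 0.7, size=(60, 3))
    return ItemResponseMatrix.from_values(vals)
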