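import numpy as np
import pytest

from ppdkin import REFERENCE_RATE_CONSTANTS, default_network


@pytest.fixture(scope="session")
def network():
    return default_network()


@pytest.fixture(scope="session")
def k_ref():
    """Reference fitted rate constants (min^-1), k8 = k9 = 0."""
    return REFERENCE_RATE_CONSTANTS.copy()


@pytest.fixture(scope="session")
def c0_pure_a():
    c0 = np.zeros(9)
    c0[0] = 1.0
    return c0


@pytest.fixture(scope="session")
def grid_10():
    """The default sampling design: 10 equally spaced times on [0, 360] min."""
    return np.linspace(0.0, 360.0, 10)


def random_rate_vectors(n, seed=0, scale=1e-2):
    """Random nonnegative k draws, mixed magnitudes, some entries zeroed."""
    rng = np.random.default_rng(seed)
    draws = []
    for _ in range(n):
        k = rng.uniform(0.0, scale, size=12)
        if rng.random() < 0.3:
            k[rng.integers(0, 12)] = 0.0
        draws.append(k)
    return draws
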