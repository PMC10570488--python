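import numpy as np
import pytest

from tractwmh import build_phantom_space


@pytest.fixture(scope="session")
def space64():
    return build_phantom_space((64, 64, 64), (1.0, 1.0, 1.2), seed=7)


@pytest.fixture(scope="session")
def space32():
    """Smallest legal grid; used for brute-force oracle comparisons."""
    return build_phantom_space((32, 32, 32), (1.0, 1.0, 1.2), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(20230803)
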