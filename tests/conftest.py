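import numpy as np
import pytest

from diasim.library_io import generate_synthetic_library


@pytest.fixture(scope="session")
def small_library():
    """50 seeded synthetic precursors shared across tests."""
    return generate_synthetic_library(50, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
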