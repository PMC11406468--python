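import numpy as np
import pytest

from muellermap import random_physical_mueller


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def physical_ensemble():
    """1,000 random physically realizable Mueller matrices (seeded)."""
    rng = np.random.default_rng(7)
    return np.stack(
        [random_physical_mueller(rng, n_pure_components=1 + i % 5) for i in range(1000)]
    )
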