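import numpy as np
import pytest
from hypothesis import settings

from fuzzycomplex import synthetic as syn

settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")


@pytest.fixture(scope="session")
def toy_complex():
    """Planted host-guest helix complex with truth-derived restraints."""
    return syn.gen_toy_complex(seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
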