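import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def small_two_region():
    """Fast 100x100 two-value phantom (object 170 / background 85)."""
    from lgfiseg import make_two_region

    return make_two_region(shape=(100, 100), seed=11)
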