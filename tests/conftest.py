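import numpy as np
import pytest

from nchr.nlreg import PatchConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cfg():
    """3x3 patches in a 5x5 neighborhood — the brute-force oracle scale."""
    return PatchConfig(patch_size=3, neighborhood_size=5)
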