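import numpy as np
import pytest

from bullseye import InitialState, ModelParams


@pytest.fixture(scope="session")
def wt_params():
    """Wild-type defaults (distal base rates, neutral ratios)."""
    return ModelParams()


@pytest.fixture(scope="session")
def default_init():
    return InitialState()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
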