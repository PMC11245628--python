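import numpy as np
import pytest

from timescales.filterbank import default_bands, design_filter_bank


@pytest.fixture(scope="session")
def bank():
    """Default eight-band filter bank (shared; design is deterministic)."""
    return design_filter_bank()


@pytest.fixture(scope="session")
def bands():
    return default_bands()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
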