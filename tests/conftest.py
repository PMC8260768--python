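import numpy as np
import pytest
from hypothesis import settings

from tallfusion import synthetic_data as sd

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_whitelist():
    return sd.random_whitelist(4, seed=11)


@pytest.fixture(scope="session")
def clean_longreads(small_whitelist):
    """Error-free simulated reads from 4 cells, with truth and markers."""
    reads, truth, markers = sd.simulate_longreads(
        small_whitelist, n_cells=4, reads_per_cell=12,
        fusion_fraction=0.5, sub_error_rate=0.0, seed=21,
    )
    return reads, truth, markers
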