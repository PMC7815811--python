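import numpy as np
import pytest

from dfcpipe.connectivity import WindowSpec
from dfcpipe.core import RegionTimeSeries
from dfcpipe.synthetic import make_correlation_profile, simulate_stationary_series


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def window_spec():
    return WindowSpec()


@pytest.fixture
def small_profile():
    return make_correlation_profile(6, 0.3, seed=7)


@pytest.fixture
def stationary_ts(small_profile):
    return simulate_stationary_series(
        small_profile, n_volumes=200, tr=2.2, seed=11, subject_id="sub-01"
    )


@pytest.fixture
def random_ts(rng):
    values = rng.standard_normal((5, 120))
    return RegionTimeSeries(
        values=values, tr=2.2, region_labels=[f"r{i}" for i in range(5)],
        subject_id="sub-rand",
    )
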