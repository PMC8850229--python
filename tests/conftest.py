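import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from kmdkit import MMParams

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def alcohol_params():
    """Ground truth of the worked example: hepatic alcohol dehydrogenase."""
    return MMParams(vmax=175.0, km=11.8)


@pytest.fixture
def table1_grid():
    """Half-hour grid used for the printed slope table."""
    return np.arange(0.0, 12.51, 0.5)
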