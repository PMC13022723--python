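import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def fine_grid():
    """Dense wavenumber grid around the Qy region for oracle comparisons."""
    return np.arange(12500.0, 16500.0, 0.2)
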