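import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def calib_markers():
    """Marker positions of the standard calibration chromosome
    (100 cM, 5 markers/cM)."""
    from texqtl.genome import build_genome

    return build_genome(1, 100, 5).marker_pos_cm[0]
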