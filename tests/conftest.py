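import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def grid96():
    """The default assay grid: 0-96 h every 15 min (385 points)."""
    from phagecentroid import default_time_grid

    return default_time_grid()


@pytest.fixture
def rng():
    return np.random.default_rng(20240531)


@pytest.fixture
def flat_control():
    """Constant OD 0.4 on hours 0..3 — the simplest positive-area control."""
    from phagecentroid import GrowthCurve

    return GrowthCurve("ctrl", np.arange(4.0), np.full(4, 0.4))
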