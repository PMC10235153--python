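import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")

#: Small-image overrides for Monte-Carlo-heavy tests (layout still fits).
SMALL = dict(image_height=48, image_width=152, roi_size=20)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def default_params():
    from ishpattern import AnalysisParams

    return AnalysisParams()
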