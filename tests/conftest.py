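import pytest
from hypothesis import HealthCheck, settings

from nsclc_cea.params import default_parameters, set_value

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def base():
    """The published base-case parameter set."""
    return default_parameters()


@pytest.fixture
def calibrated(base):
    """Base case with the post-treatment utility calibrated to the
    published arm QALYs (u_post_treatment = 0.98)."""
    return set_value(base, "utilities.u_post_treatment", 0.98)
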