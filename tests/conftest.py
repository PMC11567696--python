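import pytest
from hypothesis import HealthCheck, settings

from diffrate import datasets

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: Published probe diffusion coefficient used throughout (m^2/s).
D_PROBE = datasets.PROBE_DIFFUSION_M2_S


@pytest.fixture(scope="session")
def reference_dataset():
    """The six embedded YOYO-1 / lambda-DNA measurements."""
    return datasets.binding_rate_dataset()
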