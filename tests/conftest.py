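import pytest
from hypothesis import HealthCheck, settings

from oleoflux.synthetic_models import build_toy_gem, toy_baseline_composition

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def toy_model():
    return build_toy_gem()


@pytest.fixture(scope="session")
def baseline_composition():
    return toy_baseline_composition()
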