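import pytest
from hypothesis import HealthCheck, settings

from aquarisk.synthetic import generate_study_dataset

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def study_samples():
    """One full synthetic study dataset (108 samples, 36 locations)."""
    return generate_study_dataset(seed=7)
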