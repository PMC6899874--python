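import dataclasses

import pytest
from hypothesis import HealthCheck, settings

import shamblind as sb

settings.register_profile(
    "default",
    max_examples=50,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_cohort():
    """A full 32-participant cohort under default (null RT effect) conditions."""
    return sb.generate_cohort(seed=0)


@pytest.fixture(scope="session")
def small_cohort():
    """An 8-participant cohort for fast structural tests."""
    cfg = dataclasses.replace(sb.GeneratorConfig(), n_participants=8)
    return sb.generate_cohort(cfg, seed=42)
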