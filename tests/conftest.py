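import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from growthfit.registry import builtin_registry

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry():
    """A fresh built-in registry shared across the test session."""
    return builtin_registry()


@pytest.fixture
def dense_grid():
    return np.linspace(0.0, 60.0, 301)
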