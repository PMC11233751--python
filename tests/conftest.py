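import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")

from amphihap.simulate import SimulationSpec


@pytest.fixture
def small_spec():
    """Reduced study conditions: short nrDNA carrier, 20 kb plastome."""
    return SimulationSpec(
        seed=1,
        reference_length=600,
        flank_length=30,
        plastome_length=20000,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
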