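import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def compiled_aligner():
    """Trigger numba compilation once so individual tests stay fast."""
    from circfuse.align_core import local_align

    local_align("ACGT", "ACGT")
    return local_align
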