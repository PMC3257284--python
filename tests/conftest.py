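import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_panel():
    """Ancestor-like flow panel at reduced event count (fast unit tests)."""
    from lacprofiler import FlowSimParams, generate_flow_panel

    params = FlowSimParams(seed=7, n_events=6000)
    return generate_flow_panel(params)


@pytest.fixture(scope="session")
def spill():
    from lacprofiler.flow import SpilloverMatrix

    return SpilloverMatrix()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
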