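import numpy as np
import pytest

from dircuff.synth import Protocol, ScenarioConfig, simulate_recording


@pytest.fixture(scope="session")
def short_protocol() -> Protocol:
    """Desk-scale obstruction protocol used by the heavier integration tests."""
    return Protocol(baseline_s=30.0, n_obstructions=3, obstruction_s=15.0, gap_s=20.0, post_s=15.0)


@pytest.fixture(scope="session")
def intact_recording(short_protocol):
    return simulate_recording(ScenarioConfig(condition="intact", protocol=short_protocol, seed=11))


@pytest.fixture(scope="session")
def noise_recording(short_protocol):
    return simulate_recording(
        ScenarioConfig(condition="complete_transection", protocol=short_protocol, seed=770)
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
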