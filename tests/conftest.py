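import pytest

from fcmid.simulate import SimulationConfig


@pytest.fixture
def small_config():
    """Down-scaled study for fast end-to-end tests (same structure)."""
    return SimulationConfig(seed=7, n_baseline_features=200, n_spike_artifacts=8)


@pytest.fixture
def default_config():
    return SimulationConfig(seed=0)
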