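import pytest

from medipdmr.synthetic_data import SimulationConfig


@pytest.fixture
def small_config() -> SimulationConfig:
    """Scaled-down study conditions for fast unit tests."""
    return SimulationConfig(n_promoters=8, n_mirnas=40, n_genes=60, seed=11)


@pytest.fixture
def clean_config() -> SimulationConfig:
    """Noise-free variant: planted effects are realized exactly."""
    return SimulationConfig(
        n_promoters=8, n_mirnas=40, n_genes=60, noise_sd=0.0, seed=11
    )
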