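import numpy as np
import pytest

from engramfield.field_model import BidomainParams
from engramfield.synthetic import GeneratorConfig, channel_positions, default_ensemble


@pytest.fixture(scope="session")
def positions16():
    return channel_positions(16, 2.0)


@pytest.fixture(scope="session")
def bidomain():
    return BidomainParams(sigma_e=1.0, sigma_i=1.0, a_mm=0.1, y_mm=0.5)


@pytest.fixture(scope="session")
def small_ensemble(positions16):
    return default_ensemble(
        positions16, kernel_amplitude=0.08, kernel_width_mm=0.12, noise_sd=0.02
    )


@pytest.fixture(scope="session")
def small_recording(positions16, small_ensemble):
    """A small cue-conditioned recording shared across read-only tests."""
    from engramfield.synthetic import simulate_recording

    cfg = GeneratorConfig(
        n_trials=8,
        n_channels=16,
        delay_ms=150.0,
        cue_angles_deg=(0.0, 120.0, 240.0),
        ensemble=small_ensemble,
        cue_amplitude=0.01,
        master_seed=42,
    )
    return simulate_recording(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
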