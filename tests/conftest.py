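import numpy as np
import pytest

from bracemech import ForceRotationTrace, ProtocolConfig, simulate_trace


@pytest.fixture
def clean_protocol() -> ProtocolConfig:
    """Noise-free, hysteresis-free protocol: slope recovery must be exact."""
    return ProtocolConfig(noise_sd_N=0.0, hysteresis_factor=1.0)


@pytest.fixture
def hysteretic_protocol() -> ProtocolConfig:
    """Noise-free but hysteretic (unloading slope = 0.8 * loading slope)."""
    return ProtocolConfig(noise_sd_N=0.0, hysteresis_factor=0.8)


@pytest.fixture
def clean_trace(clean_protocol) -> ForceRotationTrace:
    return simulate_trace(50.0, clean_protocol, seed=0)


@pytest.fixture
def two_sample_trace() -> ForceRotationTrace:
    return ForceRotationTrace(
        index=np.array([0, 1]),
        rotation_deg=np.array([0.0, 5.0]),
        force_N=np.array([0.0, 2.5]),
        load_height_m=0.64,
        plant_id="p1",
        test_label="A",
    )
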