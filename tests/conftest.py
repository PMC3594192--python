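from dataclasses import replace

import numpy as np
import pytest

from smforce import SimulationConfig, simulate_force_curve


@pytest.fixture
def control_config():
    return SimulationConfig(seed=1)


@pytest.fixture
def noiseless_config(control_config):
    return replace(control_config, force_noise_sd=0.0, baseline_tilt=0.0)


@pytest.fixture
def single_event_curve(noiseless_config):
    """Noiseless curve with one tether rupturing at 132 pN (Lc = 35 nm)."""
    return simulate_force_curve(noiseless_config, [(132.0, 35.0)])


@pytest.fixture
def rng():
    return np.random.default_rng(1)
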