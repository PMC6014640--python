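import numpy as np
import pytest

from fhrcluster.synth_aecg import generate_aecg, scenario_preset


@pytest.fixture(scope="session")
def scenario1_recording():
    """60-s low fetal/maternal amplitude-ratio fixture (amplitude regime)."""
    return generate_aecg(scenario_preset("scenario1", seed=7))


@pytest.fixture(scope="session")
def scenario2_recording():
    """60-s comparable-amplitude, narrow-fetal-QRS fixture (product regime)."""
    return generate_aecg(scenario_preset("scenario2", seed=7))


@pytest.fixture(scope="session")
def clean_scenario1_recording():
    """Noise- and wander-free scenario-1 fixture (beat trains only)."""
    return generate_aecg(scenario_preset("scenario1", seed=7, noise_sd=0.0, wander_amp=0.0))


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
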