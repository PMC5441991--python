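import numpy as np
import pytest

from bccancel.config import ExperimentConfig, JitterConfig, ObserverConfig
from bccancel.head_model import make_reference_model
from bccancel.pipeline import simulate_experiment


@pytest.fixture(scope="session")
def model():
    return make_reference_model(seed=1)


@pytest.fixture(scope="session")
def noiseless_observer():
    return ObserverConfig(level_noise_db=0.0, phase_noise_deg=0.0)


@pytest.fixture(scope="session")
def zero_jitter():
    return JitterConfig(gain_sd_db=0.0, phase_sd_deg=0.0,
                        contra_slope_sd_deg_per_khz=0.0)


@pytest.fixture(scope="session")
def noiseless_exp1(noiseless_observer, zero_jitter):
    """Full simulated fine-grid experiment with a perfect observer."""
    cfg = ExperimentConfig(
        experiment="exp1", model_seed=1, run_seed=1,
        observer=noiseless_observer, jitter=zero_jitter,
    )
    return simulate_experiment(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
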