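import numpy as np
import pytest

from streamselect.pipeline import ExperimentConfig
from streamselect.simulate import (
    SelectionModel,
    SimulationConfig,
    make_category_patterns,
    make_response_kernels,
)


@pytest.fixture(scope="session")
def kernels():
    return make_response_kernels(sfreq=100.0)


@pytest.fixture(scope="session")
def patterns30():
    return make_category_patterns(n_sensors=30, rng_seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """Smallest simulation that still exercises every code path."""
    return SimulationConfig(n_sensors=30, n_localizer_trials=40,
                            n_rsvp_trials=8, n_subjects=2, rng_seed=3,
                            noise_sd=0.5)


@pytest.fixture
def tiny_experiment(tiny_config):
    return ExperimentConfig(sim=tiny_config, model=SelectionModel())
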