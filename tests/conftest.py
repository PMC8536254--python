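import numpy as np
import pytest

from smkin.simulate import KineticScheme, SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def uife_scheme():
    return KineticScheme(sub_step_lifetimes_s=(3.0, 4.5))


@pytest.fixture
def quiet_config():
    """Noiseless rendering config with a single Class-II trace slot."""
    return SimulationConfig(
        frame_s=0.05,
        duration_s=60.0,
        shot_noise=False,
        read_noise_sd=0.0,
        estar_noise_sd=0.0,
        binding_time_range=(0.0, 0.0),
        n_traces=1,
        seed=0,
    )
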