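import numpy as np
import pytest

from tacsmep.synthetic import GenerationConfig, generate_session


@pytest.fixture(scope="session")
def short_config():
    """A 30 s single-block session at defaults otherwise — fast fixture."""
    return GenerationConfig(seed=11, n_blocks=1, block_duration=30.0)


@pytest.fixture(scope="session")
def short_session(short_config):
    return generate_session(short_config)


@pytest.fixture(scope="session")
def clean_config():
    """Noiseless short session: exact oracle for phase and amplitude."""
    return GenerationConfig(
        seed=12,
        n_blocks=1,
        block_duration=30.0,
        monitor_noise_sd=0.0,
        emg_noise_sd=0.0,
        trial_noise=0.0,
        precontraction_rate=0.0,
        p_tms=1.0,
    )


@pytest.fixture(scope="session")
def clean_session(clean_config):
    return generate_session(clean_config)


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
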