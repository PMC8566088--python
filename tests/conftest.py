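import numpy as np
import pytest

from gaitmark.synthgait import GeneratorConfig, generate_day


@pytest.fixture(scope="session")
def clean_cfg():
    """Noise-free, pulse-free generator: exact recovery must hold."""
    return GeneratorConfig(noise_sd=0.0, pulse_rate=0.0,
                           pressure_noise_sd=0.0, seed=3)


@pytest.fixture(scope="session")
def clean_day(clean_cfg):
    rec, truth = generate_day(clean_cfg, n_cycles_per_pattern=4)
    return rec, truth


@pytest.fixture(scope="session")
def noisy_day():
    cfg = GeneratorConfig(noise_sd=0.3, seed=7)
    rec, truth = generate_day(cfg, n_cycles_per_pattern=6,
                              schedule="grouped")
    return rec, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
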