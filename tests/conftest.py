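import numpy as np
import pytest

import hopwave as hw


@pytest.fixture(scope="session")
def bank():
    return hw.build_filter_bank()


@pytest.fixture(scope="session")
def clean_config():
    """Noise-free, line-free configuration: exact ground-truth recovery."""
    return hw.SimulationConfig(noise_sd=0.0, line_amplitude=0.0, seed=11)


@pytest.fixture(scope="session")
def clean_trial(clean_config):
    trial, truth = hw.generate_trial(clean_config, "ACLR", "index", "SUBJ-A", 0)
    return trial, truth


@pytest.fixture(scope="session")
def noisy_trial():
    cfg = hw.SimulationConfig(seed=23)
    trial, truth = hw.generate_trial(cfg, "Control", "contralateral", "SUBJ-B", 1)
    return trial, truth


@pytest.fixture(scope="session")
def small_cohort():
    """A small processed cohort shared by the slower integration tests."""
    cfg = hw.SimulationConfig(n_per_group=(3, 3), seed=5)
    cohort = hw.generate_cohort(cfg)
    patterns = hw.process_cohort(cohort)
    return cohort, patterns


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
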