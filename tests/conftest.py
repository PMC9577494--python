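import numpy as np
import pytest

from emofuse import SimulationConfig, features_table, simulate_dataset


@pytest.fixture(scope="session")
def strong_config():
    """Strong arousal effect, noise off: features are cleanly separable."""
    return SimulationConfig(
        n_subjects=12, trials_per_subject=10, trial_duration_s=45.0,
        arousal_effect=2.0, noise_sd_ecg=0.0, noise_sd_eda=0.0, noise_sd_rsp=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def strong_trials(strong_config):
    return simulate_dataset(strong_config)


@pytest.fixture(scope="session")
def strong_study_trials(strong_trials):
    return [t for t in strong_trials if not t.is_baseline]


@pytest.fixture(scope="session")
def strong_features(strong_trials):
    return features_table(strong_trials)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
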