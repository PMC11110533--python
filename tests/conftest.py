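import numpy as np
import pytest

from fnirsglu import SyntheticConfig, generate_cohort


def tiny_config(seed: int = 7, **overrides) -> SyntheticConfig:
    """A small but structurally complete study: 3 subjects, 6 channels
    (2 coupled), 2 min fasting + 8 min post-load at 5 Hz."""
    base = dict(
        n_subjects=3, n_channels=6, sampling_rate=5.0,
        fasting_duration=120.0, glucose_duration=480.0,
        coupled_channels=frozenset({2, 5}),
        peak_time_mean=180.0, peak_time_sd=30.0,
        glucose_sample_interval=60.0, rng_seed=seed)
    base.update(overrides)
    return SyntheticConfig(**base)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(tiny_config())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
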