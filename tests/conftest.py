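import numpy as np
import pytest

from pttbp import SimConfig, simulate_feature_dataset, simulate_subject


@pytest.fixture(scope="session")
def clean_subject():
    """A noise-free, drift-free 60 s subject at 125 Hz with known truth."""
    cfg = SimConfig(duration_s=60.0, fs=125.0, hr_bpm=75.0, ptt_s=0.25, seed=1)
    record, gt = simulate_subject(cfg)
    return cfg, record, gt


@pytest.fixture(scope="session")
def small_feature_ds():
    return simulate_feature_dataset(400, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
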