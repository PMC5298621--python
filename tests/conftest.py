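import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fbgbp as F

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_config():
    """Two fast subjects (low fs, short records) for workflow-level tests."""
    subjects = [
        dataclasses.replace(p, ref_noise_sd=1.0)
        for p in F.default_subjects()[:2]
    ]
    return F.ExperimentConfig(
        subjects=subjects,
        n_cal=6,
        n_val=4,
        duration_s=6.0,
        fs=500.0,
        seed=0,
        k_max=3,
    )


@pytest.fixture(scope="session")
def tiny_report(tiny_config):
    return F.run_experiment(tiny_config)


def periodic_pulse(params, bp, n_periods, fs, hr_bpm=None):
    """Noise-free tiled beat template (no interferometer), for oracles."""
    hr = hr_bpm or params.heart_rate_bpm
    n = int(round(60.0 / hr * fs))
    tpl = F.make_beat_template(params, bp, n)
    return np.tile(tpl, n_periods)
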