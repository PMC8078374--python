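import numpy as np
import pytest

import wristox as wx
from wristox.config import RunConfig
from wristox.pipeline import train_models


@pytest.fixture(scope="session")
def constants():
    return wx.OpticalConstants.default()


@pytest.fixture(scope="session")
def clean_record():
    """60 s of noise- and motion-free PPG at a constant 97% saturation."""
    subject = wx.SubjectParams(motion_rate=0.0, noise_sd=0.0)
    return wx.synthesize_ppg(
        subject, np.array([0.0, 60.0]), np.array([0.97, 0.97]), fs=25.0, duration=60.0, seed=11
    )


@pytest.fixture(scope="session")
def small_config():
    return RunConfig()


@pytest.fixture(scope="session")
def small_study():
    return wx.simulate_study(n_subjects=2, seed=4242)


@pytest.fixture(scope="session")
def trained_models(small_config):
    """Models trained at the default training scale; shared across tests."""
    train_study = wx.simulate_study(n_subjects=small_config.n_train_subjects, seed=515)
    return train_models(train_study, small_config, seed=99)


def plateau_record(saturation: float, seed: int = 0, duration: float = 60.0,
                   noise_sd: float = 0.0, motion_rate: float = 0.0, **kwargs):
    """Constant-saturation record helper used across test modules."""
    subject = wx.SubjectParams(motion_rate=motion_rate, noise_sd=noise_sd)
    return wx.synthesize_ppg(
        subject,
        np.array([0.0, duration]),
        np.array([saturation, saturation]),
        fs=25.0,
        duration=duration,
        seed=seed,
        **kwargs,
    )
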