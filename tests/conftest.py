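import numpy as np
import pytest

from earoddball import paradigm, synthgen


@pytest.fixture(scope="session")
def rapid_schedule():
    return paradigm.generate_schedule("rapid", seed=7)


@pytest.fixture(scope="session")
def sporadic_schedule():
    return paradigm.generate_schedule("sporadic", seed=7)


@pytest.fixture(scope="session")
def short_schedule():
    """A 20-trial rapid-paced block for fast EEG tests."""
    return paradigm.generate_schedule("rapid", seed=3, n_trials=20)


@pytest.fixture(scope="session")
def quiet_profile():
    """Noise-free generative profile with no between-participant spread."""
    return synthgen.ParticipantProfile(
        noise_uv_rms=0.0,
        white_noise_uv=0.0,
        erp_random_sds=(0.0, 0.0),
        rt_random_sds=(0.0, 0.0),
        miss_random_sds=(0.0, 0.0),
    )


@pytest.fixture(scope="session")
def small_config():
    return synthgen.SessionConfig(n_participants=2, calibration_s=60.0)


@pytest.fixture(scope="session")
def noisy_recording(short_schedule, small_config):
    """A realistic-noise recording of the short block."""
    return synthgen.simulate_eeg(
        synthgen.ParticipantProfile(), short_schedule, small_config, seed=11
    )


@pytest.fixture(scope="session")
def quiet_recording(short_schedule, quiet_profile, small_config):
    return synthgen.simulate_eeg(quiet_profile, short_schedule, small_config, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
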