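import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from actimage.cli import build_images
from actimage.imu_io import IMU_CHANNELS, ImuRecording

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def hs_clean_images():
    """Noise-free separable 4-class cohort (199 windows) as images."""
    return build_images(cohort="HS", seed=1, noise_sd=0.0)


@pytest.fixture(scope="session")
def ss_noisy_images():
    """Noisy imbalanced 4-class cohort (173 windows) as images."""
    return build_images(cohort="SS", seed=1)


@pytest.fixture()
def small_recording():
    """4-sample, 6-channel labeled recording."""
    rng = np.random.default_rng(7)
    return ImuRecording(
        sample_rate=100.0,
        channels=IMU_CHANNELS,
        data=rng.normal(size=(6, 4)),
        labels=np.array(["walking"] * 4, dtype=object),
        subject_id="s01",
        cohort="HS",
    )
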