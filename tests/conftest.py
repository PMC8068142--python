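import numpy as np
import pytest

from plifscan import PlatformTrajectory, SystemConfig


@pytest.fixture(scope="session")
def standard_config() -> SystemConfig:
    """The standard instrument configuration (2048 px sensor, 4x binning)."""
    return SystemConfig()


@pytest.fixture(scope="session")
def small_config() -> SystemConfig:
    """Scaled-down sensor for simulator round trips; same optics/kinematics."""
    return SystemConfig(sensor_pixels=64, bin_factor=2)


@pytest.fixture(scope="session")
def full_track() -> PlatformTrajectory:
    return PlatformTrajectory(
        start_position_mm=0.0,
        speed_mm_s=100.0,
        direction=1,
        turnaround_low_mm=0.0,
        turnaround_high_mm=500.0,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
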