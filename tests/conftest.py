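import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from smartdrive.circuit import CircuitGeometry
from smartdrive.simulate import (
    DriverProfile,
    NoiseConfig,
    designated_path_from_kinematics,
    simulate_kinematics,
    simulate_subject,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def one_lap_geometry():
    return CircuitGeometry(lap_count=1)


@pytest.fixture(scope="session")
def noiseless_lap(one_lap_geometry):
    """One noiseless lap of the standardized circuit at normal speed."""
    return simulate_kinematics(
        DriverProfile(), one_lap_geometry, "normal", noise=NoiseConfig.none(), seed=0
    )


@pytest.fixture(scope="session")
def noiseless_session():
    """Full 10-lap noiseless driving phase at normal speed."""
    return simulate_kinematics(
        DriverProfile(), CircuitGeometry(), "normal", noise=NoiseConfig.none(), seed=0
    )


@pytest.fixture(scope="session")
def clean_subject():
    """One complete simulated subject with default noise and no path errors."""
    return simulate_subject(DriverProfile(), subject_id="SCLEAN", seed=11)


@pytest.fixture(scope="session")
def designated_path(noiseless_session):
    return designated_path_from_kinematics(noiseless_session)
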