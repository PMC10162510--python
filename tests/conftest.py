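import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from wantpred import CohortConfig, simulate_cohort
from wantpred.profiles import SubjectProfile, TrajectoryPoint

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_linear_trajectory(
    t0=0.0, t1=10.0, hr0=100.0, hr1=190.0, speed0=8.0, speed1=18.0, slope=0.0, n=11
):
    """Evenly sampled trajectory with linear HR and speed ramps."""
    ts = np.linspace(t0, t1, n)
    hrs = np.linspace(hr0, hr1, n)
    speeds = np.linspace(speed0, speed1, n)
    return [
        TrajectoryPoint(time=float(t), speed=float(s), slope=float(slope), hr=float(h))
        for t, s, h in zip(ts, speeds, hrs)
    ]


@pytest.fixture
def linear_trajectory():
    return make_linear_trajectory()


@pytest.fixture(scope="session")
def default_cohort():
    """The 93-subject synthetic cohort at the default configuration."""
    return simulate_cohort(CohortConfig(seed=42))


@pytest.fixture(scope="session")
def noiseless_cohort():
    """n=100 cohort with the planted model and no outcome noise."""
    return simulate_cohort(CohortConfig(n_female=43, n_male=57, noise_sd=0.0, seed=7))


@pytest.fixture
def simple_subject(linear_trajectory):
    return SubjectProfile(
        subject_id="s1",
        age=40.0,
        sex="male",
        body_mass=70.0,
        trajectory=linear_trajectory,
    )


@pytest.fixture
def pp_series():
    def _series(subjects):
        return pd.Series({s.subject_id: s.measured_pp for s in subjects})

    return _series
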