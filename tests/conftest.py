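import numpy as np
import pytest

from robokin import ArmGeometry, SimConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def arm():
    return ArmGeometry()


def minimum_jerk_segment(duration=1.2, amplitude=0.14, n=3000):
    """Noise-free straight minimum-jerk reach along +x.

    Position x(t) = A (10 tau^3 - 15 tau^4 + 6 tau^5); its speed profile is
    v = (A/D) 30 tau^2 (1-tau)^2 with mean/peak = 8/15 and dimensionless
    discrete jerk exactly 720.
    """
    t = np.linspace(0.0, duration, n)
    tau = t / duration
    x = amplitude * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
    q = np.stack([x, np.zeros_like(x)], axis=1)
    return t, q, np.array([amplitude, 0.0])


@pytest.fixture
def minjerk():
    return minimum_jerk_segment()


@pytest.fixture(scope="session")
def small_cohort():
    """Small full cohort shared by integration tests (8 patients x 2
    sessions, 8 reaches per pointing task)."""
    cfg = SimConfig(
        n_patients=8, sessions_per_patient=2, seed=7, n_reaches=8, n_circle_reps=4
    )
    return cfg, simulate_cohort(cfg)
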