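import numpy as np
import pytest

from drowsefuse.signal_core import Condition, Session


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_session(n_seconds: float = 60.0, rate: float = 30.0, seed: int = 0, **overrides) -> Session:
    """A small random-but-valid session for unit tests."""
    g = np.random.default_rng(seed)
    n = int(round(n_seconds * rate))
    fields = {
        "lateral_position": np.clip(1.875 + 0.3 * g.standard_normal(n), 0.0, 3.75),
        "steering_angle": 5.0 * g.standard_normal(n),
        "heading_error": np.clip(g.standard_normal(n), -10, 6),
        "eye_closure": g.uniform(0.0, 1.0, n),
    }
    fields.update(overrides)
    return Session(
        subject_id="U1",
        condition=Condition.NSD,
        sample_rate=rate,
        **fields,
    )


@pytest.fixture
def session():
    return make_session()


@pytest.fixture(scope="session")
def default_cohort():
    """One small cohort shared by the tests that need realistic data."""
    from drowsefuse.synthetic import CohortConfig, generate_cohort

    return generate_cohort(CohortConfig(n_drivers=4), seed=7)
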