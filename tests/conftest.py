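import numpy as np
import pytest

import ordtrial as ot


@pytest.fixture(scope="session")
def default_pop():
    return ot.make_synthetic_population(seed=1)


@pytest.fixture(scope="session")
def small_trial(default_pop):
    """A 60-participant null trial shared by read-only tests."""
    rng = np.random.default_rng(123)
    return ot.simulate_trial(default_pop, 60, 0.0, rng)


def make_record(pid, arm, left_ml, right_ml, baseline, followup=None):
    return ot.ParticipantRecord(
        id=pid,
        arm=arm,
        constellation=ot.Constellation(left_ml, right_ml),
        baseline=np.asarray(baseline, dtype=int),
        followup=None if followup is None else np.asarray(followup, dtype=int),
    )


@pytest.fixture
def record_factory():
    return make_record
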