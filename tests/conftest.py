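import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import whiskpc as w

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_protocol():
    """50 pre-phase puffs at 0.5 Hz: enough trials for PSTHs, cheap."""
    return w.gen_protocol(n_pre=50, n_induction=0, n_post=0)


@pytest.fixture(scope="session")
def full_protocol():
    """The study protocol: 100 pre, 80-puff 4 Hz induction, 100 post."""
    return w.gen_protocol(n_pre=100, n_induction=80, n_post=100)


@pytest.fixture(scope="session")
def default_unit(small_protocol):
    return w.gen_purkinje_unit(small_protocol, w.UnitParams(seed=11))


@pytest.fixture(scope="session")
def coupled_session():
    """Session with a planted 20 ms spike->whisker coupling lag and no
    CS-trial bonus, for correlation analyses."""
    protocol = w.gen_protocol(n_pre=100, n_induction=0, n_post=0)
    train = w.gen_purkinje_unit(protocol, w.UnitParams(seed=21))
    trace = w.gen_whisker_session(
        protocol, train,
        w.WhiskerParams(seed=22, coupling_gain=0.03, coupling_lag=20.0,
                        cs_trial_bonus=0.0),
    )
    return protocol, train, trace


def relative_ss_ms(train, onsets, window=(-200.0, 300.0)):
    return [
        (train.ss_times[(train.ss_times >= o + window[0] / 1e3)
                        & (train.ss_times < o + window[1] / 1e3)] - o) * 1e3
        for o in np.asarray(onsets)
    ]
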