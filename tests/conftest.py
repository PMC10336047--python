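import numpy as np
import pytest

from dyadsync.synthetic import BehaviorSimConfig, simulate_dyad_behavior
from dyadsync.task_behavior import FeedbackEvent, Session, TrialSpec


def make_session(estimates, peer_estimates=None, participant_id="p0"):
    """Session from per-trial (est1, est2, est3) tuples; peer defaults to a
    constant 60.  Trial specs are filled with a fixed valid stimulus."""
    n = len(estimates)
    if peer_estimates is None:
        peer_estimates = [(60.0, 60.0, 60.0)] * n
    trials = [
        TrialSpec(t, t // 25 + 1, "horizontal", 40, 90, 65.0) for t in range(n)
    ]
    feedback = [
        FeedbackEvent(t, rep, estimates[t][rep - 1],
                      peer_estimates[t][rep - 1], 3 * t + rep - 1)
        for t in range(n)
        for rep in (1, 2, 3)
    ]
    return Session(participant_id=participant_id, dyad_id="d0", role="A",
                   trials=trials, feedback=feedback)


@pytest.fixture(scope="session")
def full_dyad():
    """One full synthetic dyad (100 trials) with its ground truth."""
    dyads, truth = simulate_dyad_behavior(BehaviorSimConfig(n_dyads=1, seed=7))
    return dyads[0], truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
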