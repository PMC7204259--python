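"""Shared fixtures: small synthetic sessions reused across test modules."""

import numpy as np
import pytest

import wristsyn as ws


def small_protocol(with_force: bool = False):
    protocol = [ws.TrialSpec("comfortable_max") for _ in range(3)] + [
        ws.TrialSpec("grip_only") for _ in range(3)
    ]
    if with_force:
        protocol += [ws.TrialSpec("force_max"), ws.TrialSpec("force_quarter")]
    return protocol


@pytest.fixture(scope="session")
def noiseless_session():
    gt = ws.make_ground_truth(seed=1, noise_snr_db=None)
    return ws.generate_session(gt, small_protocol(), seed=1)


@pytest.fixture(scope="session")
def noiseless_trials(noiseless_session):
    return ws.preprocess_session(noiseless_session)


@pytest.fixture(scope="session")
def noisy_session():
    gt = ws.make_ground_truth(seed=1, noise_snr_db=20.0)
    return ws.generate_session(gt, small_protocol(), seed=1)


@pytest.fixture(scope="session")
def noisy_trials(noisy_session):
    return ws.preprocess_session(noisy_session)


def effective_truth(session):
    """Ground-truth synergy basis in the task-peak-normalized channel space.

    Preprocessing divides each channel by its session-wide peak, so the
    basis an extraction can recover is the correspondingly row-rescaled
    (and re-normalized) true mixing matrix.
    """
    peaks = np.max(
        [np.clip(t.emg, 0, None).max(axis=0) for t in session.trials], axis=0
    )
    S = session.ground_truth.S_true / peaks[:, None]
    return S / np.linalg.norm(S, axis=0, keepdims=True)
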