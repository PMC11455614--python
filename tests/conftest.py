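import numpy as np
import pytest

from explorekit.bandit_task import SessionLog, Trial


def make_session(
    records,
    mouse_id="m0",
    session_id="s0",
    epoch="habituation",
    day=0,
    block_length=4,
):
    """Build a SessionLog from (high_spout, choice, rewarded) tuples with
    fixed-length blocks."""
    log = SessionLog(mouse_id=mouse_id, session_id=session_id, epoch=epoch, day=day)
    for i, (high, choice, rewarded) in enumerate(records):
        log.trials.append(
            Trial(
                trial_idx=i,
                block_idx=i // block_length,
                high_spout=high,
                choice=choice,
                rewarded=bool(rewarded),
                trial_in_block=i % block_length,
            )
        )
    return log


@pytest.fixture
def twelve_trial_session():
    """Hand-written 12-trial session (blocks of 4, one timeout) used by the
    enumeration oracles for switch probabilities and p(high) curves."""
    records = [
        # block 0: high = L
        ("L", "L", 1),
        ("L", "L", 1),
        ("L", "L", 0),
        ("L", "R", 0),
        # block 1: high = R
        ("R", "L", 0),
        ("R", "R", 1),
        ("R", "timeout", 0),
        ("R", "R", 1),
        # block 2: high = L
        ("L", "R", 0),
        ("L", "R", 0),
        ("L", "L", 1),
        ("L", "L", 1),
    ]
    return make_session(records)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
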