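"""Two-armed bandit task environment with block-wise reward reversals.

The environment presents two spouts, L and R. Within a block, one spout
(the "high" spout) is rewarded with probability ``p_high`` when chosen and
the other with ``p_low``. When a block's sampled length is exhausted the
spout identities reverse without any cue. Sessions have a fixed trial
budget, so the final block may be truncated; its *sampled* length is still
recorded.

Session logs round-trip through a plain CSV dialect shared by every
behavioral module (see :func:`write_sessions_csv`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BlockScheme",
    "TaskConfig",
    "Trial",
    "SessionLog",
    "FIXED_20",
    "VARIABLE_20_40",
    "STANDARD_TASK",
    "sample_block_length",
    "run_session",
    "sessions_to_frame",
    "frame_to_sessions",
    "write_sessions_csv",
    "read_sessions_csv",
]

SPOUTS = ("L", "R")
CHOICES = ("L", "R", "timeout")

SESSION_CSV_COLUMNS = [
    "mouse_id",
    "session_id",
    "epoch",
    "day",
    "trial_idx",
    "block_idx",
    "trial_in_block",
    "high_spout",
    "choice",
    "rewarded",
]


class ConfigurationError(ValueError):
    """Raised when a task or scheme description is internally inconsistent."""


@dataclass(frozen=True)
class BlockScheme:
    """Distribution of block lengths.

    ``kind`` is ``"fixed"`` (every block has ``fixed_length`` trials) or
    ``"variable"`` (lengths drawn from ``variable_lengths``, a sequence of
    ``(length, probability)`` pairs).
    """

    kind: str
    fixed_length: int | None = None
    variable_lengths: tuple[tuple[int, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "variable"):
            raise ConfigurationError(f"unknown scheme kind {self.kind!r}")
        if self.kind == "fixed":
            if self.fixed_length is None or self.fixed_length <= 0:
                raise ConfigurationError("fixed scheme needs a positive fixed_length")
        else:
            if not self.variable_lengths:
                raise ConfigurationError("variable scheme needs variable_lengths")
            lengths = [l for l, _ in self.variable_lengths]
            probs = [p for _, p in self.variable_lengths]
            if any((not isinstance(l, (int, np.integer))) or l <= 0 for l in lengths):
                raise ConfigurationError("block lengths must be positive integers")
            if any(p < 0 for p in probs):
                raise ConfigurationError("block-length probabilities must be >= 0")
            if not math.isclose(sum(probs), 1.0, abs_tol=1e-12):
                raise ConfigurationError(
                    f"block-length probabilities sum to {sum(probs)!r}, not 1"
                )

    @property
    def support(self) -> tuple[int, ...]:
        if self.kind == "fixed":
            return (int(self.fixed_length),)
        return tuple(int(l) for l, _ in self.variable_lengths)


#: Fixed 20-trial blocks (standard habituation/treatment structure).
FIXED_20 = BlockScheme(kind="fixed", fixed_length=20)

#: Variable 20/30/40-trial blocks with probabilities 0.43/0.32/0.25.
VARIABLE_20_40 = BlockScheme(
    kind="variable", variable_lengths=((20, 0.43), (30, 0.32), (40, 0.25))
)


@dataclass(frozen=True)
class TaskConfig:
    """Reward contingencies plus block scheme for one session type."""

    p_high: float = 0.8
    p_low: float = 0.2
    scheme: BlockScheme = FIXED_20
    n_trials_per_session: int = 300

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_low <= self.p_high <= 1.0):
            raise ConfigurationError(
                f"need 0 <= p_low <= p_high <= 1, got ({self.p_low}, {self.p_high})"
            )
        if self.n_trials_per_session <= 0:
            raise ConfigurationError("n_trials_per_session must be positive")


#: The 80/20 contingencies with fixed 20-trial blocks.
STANDARD_TASK = TaskConfig()


@dataclass(frozen=True)
class Trial:
    trial_idx: int
    block_idx: int
    high_spout: str
    choice: str
    rewarded: bool
    trial_in_block: int


@dataclass
class SessionLog:
    """One behavioral session: ordered trials plus identifying metadata."""

    mouse_id: str
    session_id: str
    epoch: str
    day: int
    trials: list[Trial] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.trials)

    def n_blocks(self) -> int:
        return 0 if not self.trials else self.trials[-1].block_idx + 1


def sample_block_length(scheme: BlockScheme, rng: np.random.Generator) -> int:
    """Draw one block length from the scheme."""
    if scheme.kind == "fixed":
        return int(scheme.fixed_length)
    lengths = np.array([l for l, _ in scheme.variable_lengths])
    probs = np.array([p for _, p in scheme.variable_lengths])
    return int(rng.choice(lengths, p=probs))


Policy = Callable[[Sequence[tuple[str, bool]], str], str]


def run_session(
    config: TaskConfig,
    policy: Policy,
    rng: np.random.Generator,
    *,
    mouse_id: str = "sim",
    session_id: str = "s0",
    epoch: str = "habituation",
    day: int = 0,
) -> SessionLog:
    """Run one session of the bandit task under an externally supplied policy.

    ``policy(history, high_spout)`` is called once per trial with the list of
    completed ``(choice, rewarded)`` pairs and the identity of the currently
    high spout, and must return ``"L"``, ``"R"`` or ``"timeout"``. Honest
    (non-oracle) policies must ignore the ``high_spout`` argument; it is
    exposed so that omniscient reference policies can be expressed.

    The initial high spout is drawn uniformly at random. Rewards are sampled
    independently per trial; timeouts are never rewarded and never forced by
    the environment.
    """
    log = SessionLog(mouse_id=mouse_id, session_id=session_id, epoch=epoch, day=day)
    history: list[tuple[str, bool]] = []
    high = SPOUTS[int(rng.integers(2))]
    block_idx = 0
    block_len = sample_block_length(config.scheme, rng)
    trial_in_block = 0
    for trial_idx in range(config.n_trials_per_session):
        choice = policy(history, high)
        if choice not in CHOICES:
            raise ValueError(f"policy returned invalid choice {choice!r}")
        if choice == "timeout":
            rewarded = False
        else:
            p = config.p_high if choice == high else config.p_low
            rewarded = bool(rng.random() < p)
        log.trials.append(
            Trial(
                trial_idx=trial_idx,
                block_idx=block_idx,
                high_spout=high,
                choice=choice,
                rewarded=rewarded,
                trial_in_block=trial_in_block,
            )
        )
        history.append((choice, rewarded))
        trial_in_block += 1
        if trial_in_block == block_len:
            block_idx += 1
            block_len = sample_block_length(config.scheme, rng)
            trial_in_block = 0
            high = "L" if high == "R" else "R"
    return log


# ---------------------------------------------------------------------------
# CSV dialect


def sessions_to_frame(sessions: Iterable[SessionLog]) -> pd.DataFrame:
    rows = []
    for s in sessions:
        for t in s.trials:
            rows.append(
                (
                    s.mouse_id,
                    s.session_id,
                    s.epoch,
                    s.day,
                    t.trial_idx,
                    t.block_idx,
                    t.trial_in_block,
                    t.high_spout,
                    t.choice,
                    int(t.rewarded),
                )
            )
    return pd.DataFrame(rows, columns=SESSION_CSV_COLUMNS)


def frame_to_sessions(df: pd.DataFrame) -> list[SessionLog]:
    sessions: list[SessionLog] = []
    for (mouse, sid), grp in df.groupby(["mouse_id", "session_id"], sort=False):
        grp = grp.sort_values("trial_idx")
        log = SessionLog(
            mouse_id=str(mouse),
            session_id=str(sid),
            epoch=str(grp["epoch"].iloc[0]),
            day=int(grp["day"].iloc[0]),
        )
        for r in grp.itertuples(index=False):
            log.trials.append(
                Trial(
                    trial_idx=int(r.trial_idx),
                    block_idx=int(r.block_idx),
                    high_spout=str(r.high_spout),
                    choice=str(r.choice),
                    rewarded=bool(int(r.rewarded)),
                    trial_in_block=int(r.trial_in_block),
                )
            )
        sessions.append(log)
    return sessions


def write_sessions_csv(sessions: Iterable[SessionLog], path) -> None:
    sessions_to_frame(sessions).to_csv(path, index=False)


def read_sessions_csv(path) -> list[SessionLog]:
    return frame_to_sessions(pd.read_csv(path, dtype={"mouse_id": str, "session_id": str}))
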