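"""Entropy statistics over behavioral syllable label streams.

Frame-level label streams are run-length encoded into syllable *instances*
(maximal runs of one label). Usage and transition statistics operate on
instances, not frames; consecutive instances therefore never repeat a
label. All entropies are in bits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SyllableStream",
    "UsageDistribution",
    "run_length_encode",
    "usage_stats",
    "usage_entropy",
    "outgoing_entropy",
    "read_streams_csv",
    "write_streams_csv",
]


@dataclass
class SyllableStream:
    session_id: str
    labels: np.ndarray  # frame-level syllable labels
    frame_rate: float = 30.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.size < 1:
            raise ValueError(f"stream {self.session_id!r} is empty")
        if self.labels.min() < 0:
            raise ValueError("labels must be nonnegative")


@dataclass
class UsageDistribution:
    session_id: str
    usages: dict[int, float]  # over retained syllables, renormalized
    retained: set[int] = field(default_factory=set)


def run_length_encode(labels: np.ndarray) -> np.ndarray:
    """Instance sequence: one entry per maximal run of identical labels."""
    labels = np.asarray(labels)
    if labels.size == 0:
        return labels
    change = np.flatnonzero(np.diff(labels) != 0)
    return labels[np.concatenate(([0], change + 1))]


def retained_syllables(
    streams: Iterable[SyllableStream], min_fraction: float = 0.01
) -> set[int]:
    """Syllables making up strictly more than ``min_fraction`` of all
    instances pooled across sessions."""
    pooled = np.concatenate([run_length_encode(s.labels) for s in streams])
    ids, counts = np.unique(pooled, return_counts=True)
    frac = counts / counts.sum()
    return {int(i) for i, f in zip(ids, frac) if f > min_fraction}


def usage_stats(
    streams: Sequence[SyllableStream], min_fraction: float = 0.01
) -> tuple[list[UsageDistribution], set[int]]:
    """Per-session instance-usage fractions over the globally retained set.

    The retained set is computed on the pooled corpus; each session's
    usages are then renormalized over retained syllables.
    """
    retained = retained_syllables(streams, min_fraction)
    out = []
    for s in streams:
        inst = run_length_encode(s.labels)
        ids, counts = np.unique(inst, return_counts=True)
        kept = {int(i): int(c) for i, c in zip(ids, counts) if int(i) in retained}
        total = sum(kept.values())
        usages = {i: c / total for i, c in kept.items()} if total else {}
        out.append(UsageDistribution(session_id=s.session_id, usages=usages, retained=retained))
    return out, retained


def usage_entropy(usage: UsageDistribution) -> float:
    """Shannon entropy (bits) of the usage distribution; 0 log 0 = 0."""
    p = np.array([v for v in usage.usages.values() if v > 0])
    return float(-(p * np.log2(p)).sum()) if p.size else 0.0


def outgoing_entropy(
    stream: SyllableStream, retained: set[int]
) -> tuple[dict[int, float], float]:
    """Per-syllable entropy of the next-instance distribution, plus the
    session value (unweighted mean over retained syllables with at least
    one outgoing transition)."""
    inst = run_length_encode(stream.labels)
    if inst.size < 2:
        return {}, float("nan")
    per: dict[int, float] = {}
    for syl in sorted(retained):
        nxt = inst[1:][inst[:-1] == syl]
        if nxt.size == 0:
            continue
        _, counts = np.unique(nxt, return_counts=True)
        p = counts / counts.sum()
        per[int(syl)] = float(-(p * np.log2(p)).sum())
    mean = float(np.mean(list(per.values()))) if per else float("nan")
    return per, mean


# ---------------------------------------------------------------------------
# CSV dialect: session_id,frame_idx,syllable


def read_streams_csv(path) -> list[SyllableStream]:
    df = pd.read_csv(path, dtype={"session_id": str})
    streams = []
    for sid, grp in df.groupby("session_id", sort=False):
        grp = grp.sort_values("frame_idx")
        streams.append(SyllableStream(session_id=str(sid), labels=grp["syllable"].to_numpy()))
    return streams


def write_streams_csv(streams: Iterable[SyllableStream], path) -> None:
    frames = []
    for s in streams:
        frames.append(
            pd.DataFrame(
                {
                    "session_id": s.session_id,
                    "frame_idx": np.arange(len(s.labels)),
                    "syllable": s.labels,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
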