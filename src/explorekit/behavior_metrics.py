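"""Behavioral statistics over session logs.

All statistics exclude timeout trials; reward-rate summaries additionally
exclude the first block of each session. Every probability reported here is
a ratio of integer tallies, reproducible by a single pass over the logs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .bandit_task import SessionLog

__all__ = [
    "RateSummary",
    "TransitionCurve",
    "TransitionFit",
    "SwitchTable",
    "normalized_reward_rate",
    "p_high_curve",
    "fit_transition_tau",
    "conditional_switch_probs",
    "performance_criterion",
]

HISTORY_KEYS = ("RR", "RU", "UR", "UU")  # outcome pairs, older -> newer


@dataclass
class RateSummary:
    mouse_id: str
    daily: pd.DataFrame  # columns: epoch, day, rate, pct_change
    habituation_median: float


@dataclass
class TransitionCurve:
    offsets: np.ndarray  # trial offsets relative to block transition
    p_high: np.ndarray  # NaN where no eligible trials
    counts: np.ndarray


@dataclass
class TransitionFit:
    tau: float
    asymptote: float
    intercept: float
    rss: float
    valid: bool
    message: str = ""


@dataclass
class SwitchTable:
    """Per 2-trial same-spout history: occurrence count and P(switch)."""

    counts: dict[str, int] = field(default_factory=dict)
    p_switch: dict[str, float] = field(default_factory=dict)
    excluded: set[str] = field(default_factory=set)


def normalized_reward_rate(
    sessions: Iterable[SessionLog], mouse_id: str | None = None
) -> RateSummary:
    """Per-day reward rate and percent change vs the habituation median.

    Rate = rewards per non-timeout trial, pooling a day's sessions. The first
    block of every session is excluded.
    """
    rows = []
    mid = mouse_id
    for s in sessions:
        if mid is None:
            mid = s.mouse_id
        elif s.mouse_id != mid:
            raise ValueError("sessions from multiple mice; group per mouse first")
        for t in s.trials:
            if t.block_idx == 0 or t.choice == "timeout":
                continue
            rows.append((s.epoch, s.day, int(t.rewarded)))
    df = pd.DataFrame(rows, columns=["epoch", "day", "rewarded"])
    if df.empty or not (df["epoch"] == "habituation").any():
        raise ValueError(f"mouse {mid!r} has no eligible habituation trials")
    daily = (
        df.groupby(["epoch", "day"], sort=True)["rewarded"].mean().rename("rate").reset_index()
    )
    hab_median = float(daily.loc[daily["epoch"] == "habituation", "rate"].median())
    if hab_median == 0:
        raise ValueError(f"mouse {mid!r} has zero habituation reward rate")
    daily["pct_change"] = 100.0 * (daily["rate"] / hab_median - 1.0)
    return RateSummary(mouse_id=str(mid), daily=daily, habituation_median=hab_median)


def p_high_curve(
    sessions: Iterable[SessionLog], window: tuple[int, int] = (-5, 15)
) -> TransitionCurve:
    """p(high) as a function of trial offset around block transitions.

    Offset 0 is the first trial of a new block. Each trial is scored against
    its contemporaneous high spout, so negative offsets are scored against
    the old spout and nonnegative offsets against the new one. Offsets with
    zero eligible trials are NaN, never fabricated.
    """
    lo, hi = window
    offsets = np.arange(lo, hi + 1)
    high_counts = np.zeros(len(offsets), dtype=np.int64)
    totals = np.zeros(len(offsets), dtype=np.int64)
    for s in sessions:
        trials = s.trials
        # transition points: indices where a new block (>=1) starts
        starts = [i for i, t in enumerate(trials) if t.block_idx >= 1 and t.trial_in_block == 0]
        for start in starts:
            for k, off in enumerate(offsets):
                i = start + off
                if i < 0 or i >= len(trials):
                    continue
                t = trials[i]
                # stay within the two blocks adjoining this transition
                if off < 0 and t.block_idx != trials[start].block_idx - 1:
                    continue
                if off >= 0 and t.block_idx != trials[start].block_idx:
                    continue
                if t.choice == "timeout":
                    continue
                totals[k] += 1
                high_counts[k] += int(t.choice == t.high_spout)
    with np.errstate(invalid="ignore"):
        p = np.where(totals > 0, high_counts / np.maximum(totals, 1), np.nan)
    return TransitionCurve(offsets=offsets, p_high=p, counts=totals)


def _expcurve(n: np.ndarray, asym: float, p0: float, tau: float) -> np.ndarray:
    return asym - (asym - p0) * np.exp(-n / tau)


def fit_transition_tau(
    curve: TransitionCurve, weighted: bool = False
) -> TransitionFit:
    """Least-squares exponential fit p(n) = A - (A - p0) exp(-n / tau) over
    post-transition offsets n >= 0 with defined values."""
    sel = (curve.offsets >= 0) & np.isfinite(curve.p_high)
    n = curve.offsets[sel].astype(float)
    y = curve.p_high[sel]
    if len(n) < 4:
        return TransitionFit(np.nan, np.nan, np.nan, np.nan, False, "need >=4 defined offsets")
    if np.ptp(y) < 1e-12:
        return TransitionFit(np.nan, np.nan, np.nan, np.nan, False, "constant curve")
    sigma = None
    if weighted:
        c = curve.counts[sel].astype(float)
        sigma = 1.0 / np.sqrt(np.maximum(c, 1.0))
    try:
        popt, _ = curve_fit(
            _expcurve,
            n,
            y,
            p0=(max(y.max(), 0.5), y[0], 3.0),
            sigma=sigma,
            maxfev=20_000,
        )
    except RuntimeError as exc:
        return TransitionFit(np.nan, np.nan, np.nan, np.nan, False, str(exc))
    asym, p0, tau = (float(v) for v in popt)
    rss = float(np.sum((_expcurve(n, *popt) - y) ** 2))
    if tau <= 0 or not np.isfinite(tau):
        return TransitionFit(tau, asym, p0, rss, False, "nonpositive tau")
    return TransitionFit(tau=tau, asymptote=asym, intercept=p0, rss=rss, valid=True)


def conditional_switch_probs(
    sessions: Iterable[SessionLog], min_count: int = 50
) -> SwitchTable:
    """P(switch | 2-trial same-spout outcome history).

    Histories are built from consecutive non-timeout trials on the same
    spout; the outcome trial is the next non-timeout trial (timeouts are
    transparent). Outcome pair keys are ordered older -> newer with R =
    rewarded, U = unrewarded. Histories occurring <= ``min_count`` times are
    flagged excluded (strict '>' retention).
    """
    counts = {k: 0 for k in HISTORY_KEYS}
    switches = {k: 0 for k in HISTORY_KEYS}
    for s in sessions:
        seq = [(t.choice, t.rewarded) for t in s.trials if t.choice != "timeout"]
        for i in range(len(seq) - 2):
            (c1, r1), (c2, r2), (c3, _) = seq[i], seq[i + 1], seq[i + 2]
            if c1 != c2:
                continue
            key = ("R" if r1 else "U") + ("R" if r2 else "U")
            counts[key] += 1
            switches[key] += int(c3 != c2)
    table = SwitchTable()
    for k in HISTORY_KEYS:
        table.counts[k] = counts[k]
        table.p_switch[k] = switches[k] / counts[k] if counts[k] else float("nan")
        if counts[k] <= min_count:
            table.excluded.add(k)
    return table


def performance_criterion(
    daily_p_high: Sequence[float], window: int = 5, threshold: float = 0.6
) -> bool | None:
    """True iff some contiguous window of days has mean strictly above the
    threshold; None (not evaluable) with fewer than ``window`` days."""
    vals = np.asarray(daily_p_high, dtype=float)
    if len(vals) < window:
        return None
    means = np.convolve(vals, np.ones(window) / window, mode="valid")
    return bool(np.any(means > threshold))
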