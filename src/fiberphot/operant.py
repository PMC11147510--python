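"""Negative-reinforcement operant schedules and session scoring.

Sessions run with continuous photostimulation; activating the active nose
port earns a reward — a fixed-length (default 10 s) pause in stimulation,
mirrored by the house light. Two schedules are implemented:

* FR1 with timeout: every active-port event during stimulation starts a new
  pause; events during a pause are inert (they do not queue).
* Progressive ratio: the j-th pause requires round(5 * e^(0.2 j) - 5) active
  events during stimulation since the previous pause, generating the schedule
  1, 2, 4, 6, 9, 12, 15, 20, 25, 32, 40, 50, ...

The inactive port never affects stimulation state; pokes on either port are
always counted, since total port activations are themselves an outcome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "progressive_ratio_requirement",
    "progressive_ratio_schedule",
    "max_rewards",
    "OperantSession",
    "score_session",
]


def progressive_ratio_requirement(j: int) -> int:
    """Active-port activations required to earn reward j (1-based).

    round(5 * exp(0.2 * j) - 5), rounding half away from zero. No j in the
    behaviorally relevant range lands on an exact .5, so the tie rule is
    fixed purely for determinism.
    """
    if not float(j).is_integer() or j < 1:
        raise ValidationError(f"reward index j must be an integer >= 1, got {j}")
    value = 5.0 * math.exp(0.2 * int(j)) - 5.0
    return int(math.floor(value + 0.5))


def progressive_ratio_schedule(n_rewards: int) -> list[int]:
    """Requirements for rewards 1..n_rewards."""
    return [progressive_ratio_requirement(j) for j in range(1, n_rewards + 1)]


def max_rewards(session_length_s: float, pause_length_s: float) -> int:
    """Upper bound on rewards: floor(session / pause) back-to-back pauses."""
    if session_length_s <= 0 or pause_length_s <= 0:
        raise ValidationError("session_length_s and pause_length_s must be > 0")
    return int(math.floor(session_length_s / pause_length_s))


@dataclass
class OperantSession:
    """Scored session: reward times, pause intervals, counts, latencies.

    ``cumulative_active`` and ``cumulative_rewards`` are per-second records
    over [0, session_length_s] (the session end is always the last grid
    point) for cumulative-record plots.
    """

    session_length_s: float
    pause_length_s: float
    mode: Literal["FR1_pause", "progressive_ratio"]
    events: pd.DataFrame
    reward_times: list[float] = field(default_factory=list)
    pause_intervals: list[tuple[float, float]] = field(default_factory=list)
    active_count: int = 0
    inactive_count: int = 0
    latency_first_active_s: float = math.nan
    cumulative_active: np.ndarray = field(default_factory=lambda: np.zeros(1))
    cumulative_rewards: np.ndarray = field(default_factory=lambda: np.zeros(1))

    @property
    def rewards(self) -> int:
        return len(self.reward_times)

    @property
    def breakpoint(self) -> int:
        """Largest requirement completed (progressive-ratio sessions)."""
        if self.mode != "progressive_ratio" or not self.reward_times:
            return 0
        return progressive_ratio_requirement(len(self.reward_times))

    @property
    def next_requirement(self) -> int:
        if self.mode == "FR1_pause":
            return 1
        return progressive_ratio_requirement(len(self.reward_times) + 1)

    @property
    def stimulation_intervals(self) -> list[tuple[float, float]]:
        """Complement of the pause intervals within the session."""
        out = []
        cursor = 0.0
        for a, b in self.pause_intervals:
            if a > cursor:
                out.append((cursor, a))
            cursor = b
        if cursor < self.session_length_s:
            out.append((cursor, self.session_length_s))
        return out


def _as_event_frame(events) -> pd.DataFrame:
    if isinstance(events, pd.DataFrame):
        df = events[["time_s", "port"]].copy()
    else:
        df = pd.DataFrame(list(events), columns=["time_s", "port"])
    bad_ports = set(df["port"].unique()) - {"active", "inactive"}
    if bad_ports:
        raise ValidationError(f"unknown ports: {sorted(bad_ports)}")
    t = df["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) < 0):
        raise ValidationError("event timestamps must be sorted ascending")
    return df


def score_session(
    events,
    mode: Literal["FR1_pause", "progressive_ratio"],
    session_length_s: float,
    pause_length_s: float = 10.0,
) -> OperantSession:
    """Replay an event log through the schedule logic.

    ``events`` is a DataFrame with columns (time_s, port) or a sequence of
    (time_s, port) pairs, port in {"active", "inactive"}. A reward requires
    its full pause to fit before the session end (stimulation terminates at
    the session close anyway, so a pause that cannot fit earns nothing);
    this keeps rewards <= floor(session / pause) for every event stream.
    """
    if mode not in ("FR1_pause", "progressive_ratio"):
        raise ValidationError(f"unknown mode {mode!r}")
    if session_length_s <= 0 or pause_length_s <= 0:
        raise ValidationError("session_length_s and pause_length_s must be > 0")
    df = _as_event_frame(events)
    t = df["time_s"].to_numpy(dtype=float)
    if t.size and (t[0] < 0 or t[-1] > session_length_s):
        raise ValidationError("events must lie within [0, session_length_s]")

    reward_times: list[float] = []
    pause_intervals: list[tuple[float, float]] = []
    pause_until = -math.inf
    counter = 0  # active events during stimulation since the last reward (PR)
    active_times = []
    for ts, port in zip(t, df["port"]):
        if port != "active":
            continue
        active_times.append(ts)
        if ts < pause_until:
            continue  # inert during a pause; still counted above
        if mode == "FR1_pause":
            earned = True
        else:
            counter += 1
            earned = counter >= progressive_ratio_requirement(len(reward_times) + 1)
        if earned and ts + pause_length_s <= session_length_s:
            reward_times.append(ts)
            pause_intervals.append((ts, ts + pause_length_s))
            pause_until = ts + pause_length_s
            counter = 0

    active_arr = np.array(active_times)
    grid = np.arange(0.0, math.floor(session_length_s) + 1)
    if grid[-1] < session_length_s:
        grid = np.append(grid, session_length_s)
    cum_active = np.searchsorted(active_arr, grid, side="right").astype(float)
    cum_rewards = np.searchsorted(
        np.array(reward_times), grid, side="right"
    ).astype(float)
    return OperantSession(
        session_length_s=session_length_s,
        pause_length_s=pause_length_s,
        mode=mode,
        events=df,
        reward_times=reward_times,
        pause_intervals=pause_intervals,
        active_count=int((df["port"] == "active").sum()),
        inactive_count=int((df["port"] == "inactive").sum()),
        latency_first_active_s=float(active_arr[0]) if active_arr.size else math.nan,
        cumulative_active=cum_active,
        cumulative_rewards=cum_rewards,
    )
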