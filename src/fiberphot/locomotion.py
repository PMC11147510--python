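"""Velocity traces, lagged cross-correlation, and locomotion gating.

Used to ask whether signal fluctuations merely track movement: velocity is
derived from XY trajectories, correlated with the standardized signal over a
grid of lags (to allow for a temporal offset), and supra-threshold locomotion
bouts are turned into events so the same peri-event statistics that detect
stressor responses can be applied to spontaneous movement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError
from .events import Event, EventSet
from .preprocess import smooth_moving_average

__all__ = [
    "VelocityTrace",
    "CrossCorrelation",
    "compute_velocity",
    "cross_correlate",
    "gate_locomotion_epochs",
]


@dataclass
class VelocityTrace:
    """Non-negative, uniformly sampled speed (cm/s)."""

    time_s: np.ndarray
    velocity: np.ndarray
    sample_rate: float
    source: str = "provided"

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        if self.time_s.shape != self.velocity.shape:
            raise ValidationError("time_s and velocity must have equal length")
        if np.any(self.velocity < 0):
            raise ValidationError("velocity must be >= 0")

    def __len__(self) -> int:
        return self.velocity.size


def compute_velocity(
    xy_cm: np.ndarray,
    sample_rate: float,
    smooth_window: int = 1,
    time_s: np.ndarray | None = None,
    uniformity_tol: float = 1e-6,
) -> VelocityTrace:
    """Finite-difference speed from an XY trajectory (cm), optionally smoothed.

    The first sample is duplicated so the output has the input's length. If
    ``time_s`` is provided it is checked for uniform sampling at
    ``sample_rate`` within ``uniformity_tol`` seconds.
    """
    xy = np.asarray(xy_cm, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2 or xy.shape[0] < 2:
        raise ValidationError("xy_cm must be an (n>=2, 2) array")
    if time_s is not None:
        t = np.asarray(time_s, dtype=float)
        if t.size != xy.shape[0]:
            raise ValidationError("time_s length must match trajectory length")
        if np.max(np.abs(np.diff(t) - 1.0 / sample_rate)) > uniformity_tol:
            raise ValidationError("timestamps are not uniform at the stated rate")
    step = np.hypot(np.diff(xy[:, 0]), np.diff(xy[:, 1])) * sample_rate
    speed = np.concatenate([[step[0]], step])
    if smooth_window > 1:
        speed = smooth_moving_average(speed, smooth_window)
    t = (
        np.asarray(time_s, dtype=float)
        if time_s is not None
        else np.arange(xy.shape[0]) / sample_rate
    )
    return VelocityTrace(t, np.maximum(speed, 0.0), sample_rate, "trajectory-derived")


@dataclass
class CrossCorrelation:
    """Pearson correlation of two series over a grid of integer-sample lags.

    At lag L, ``r[L]`` correlates x(t) with y(t + L): a positive peak lag
    means y follows x by that delay.
    """

    lags_s: np.ndarray
    r: np.ndarray
    peak_lag_s: float
    peak_r: float


def cross_correlate(
    signal_z: np.ndarray,
    velocity_z: np.ndarray,
    max_lag_s: float,
    sample_rate: float,
) -> CrossCorrelation:
    """Lagged Pearson correlation on overlapping segments.

    The peak is the lag with the largest |r| (so a pure anticorrelation peaks
    with r = -1). Raises if any overlapping segment has zero variance.
    """
    x = np.asarray(signal_z, dtype=float)
    y = np.asarray(velocity_z, dtype=float)
    if x.size != y.size:
        raise ValidationError(f"length mismatch: {x.size} vs {y.size}")
    max_lag = int(round(max_lag_s * sample_rate))
    if max_lag < 0 or max_lag >= x.size // 2:
        raise ValidationError("max_lag_s must be non-negative and < trace length / 2")
    lags = np.arange(-max_lag, max_lag + 1)
    r = np.empty(lags.size, dtype=float)
    for i, lag in enumerate(lags):
        if lag >= 0:
            a, b = x[: x.size - lag], y[lag:]
        else:
            a, b = x[-lag:], y[: y.size + lag]
        if np.std(a) == 0.0 or np.std(b) == 0.0:
            raise ValidationError(f"zero-variance segment at lag {lag} samples")
        r[i] = stats.pearsonr(a, b).statistic
    peak = int(np.argmax(np.abs(r)))
    return CrossCorrelation(
        lags_s=lags / sample_rate,
        r=r,
        peak_lag_s=float(lags[peak] / sample_rate),
        peak_r=float(r[peak]),
    )


def gate_locomotion_epochs(
    velocity: VelocityTrace,
    threshold_cm_s: float | None = None,
    min_dur_s: float = 1.0,
) -> EventSet:
    """Onsets of sustained supra-threshold locomotion bouts.

    ``threshold_cm_s=None`` uses the per-recording 75th percentile (the gate
    is a convention; an absolute threshold may be supplied instead). A bout
    must stay above threshold for at least ``min_dur_s``. The resulting
    events feed the same peri-event machinery used for stressor responses.
    """
    v = velocity.velocity
    if threshold_cm_s is None:
        threshold_cm_s = float(np.percentile(v, 75.0))
    if threshold_cm_s <= 0:
        raise ValidationError("threshold_cm_s must be > 0")
    if min_dur_s < 0:
        raise ValidationError("min_dur_s must be >= 0")
    above = v > threshold_cm_s
    events = []
    i = 0
    n = v.size
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            if (j - i) / velocity.sample_rate >= min_dur_s - 1e-9:
                events.append(
                    Event(
                        onset_s=float(velocity.time_s[i]),
                        duration_s=(j - i) / velocity.sample_rate,
                        label="locomotion",
                    )
                )
            i = j
        else:
            i += 1
    return EventSet(events)
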