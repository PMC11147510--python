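"""Ground-truth-known synthetic photometry, behavior, and operant data.

Every generated dataset carries the statistical structure the analysis
assumes so that each downstream stage can be tested against known truth:

* exponential photobleaching decay per channel,
* event-locked Ca2+ transients (fast rise, slower decay) and sustained
  rectangular steps (feeding-type suppression, or dunk-type elevation) in the
  Ca2+ channel only,
* brief motion artifacts shared between channels at Poisson times (scaled
  into the isosbestic channel by a gain factor),
* independent Gaussian sensor noise per channel,
* behavior-state schedules, velocity traces with locomotion bouts, and
  Poisson nose-poke event streams for operant sessions.

All randomness flows through one seeded generator per call; identical seeds
give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .behavior import BehaviorTrack
from .errors import ValidationError
from .events import EventSet
from .locomotion import VelocityTrace
from .preprocess import CHANNEL_CA, CHANNEL_ISO, PhotometryRecording

__all__ = [
    "TransientEvent",
    "StepEvent",
    "VelocityParams",
    "SyntheticSpec",
    "GroundTruth",
    "transient_kernel",
    "kernel_peak_time",
    "kernel_peak_value",
    "generate_recording",
    "generate_behavior_track",
    "generate_velocity",
    "generate_operant_events",
    "baseline_sd_smoothed",
    "dunk_protocol",
    "shock_protocol",
    "feeding_protocol",
]

#: Motion artifacts are brief; their biexponential kernel shape is fixed.
ARTIFACT_RISE_TAU_S = 0.02
ARTIFACT_DECAY_TAU_S = 0.2


@dataclass(frozen=True)
class TransientEvent:
    """One Ca2+ transient: A * (1 - exp(-t/tau_r)) * exp(-t/tau_d) after onset."""

    onset_s: float
    amplitude: float
    rise_tau_s: float
    decay_tau_s: float


@dataclass(frozen=True)
class StepEvent:
    """Sustained rectangular change in the Ca2+ channel."""

    onset_s: float
    magnitude: float
    duration_s: float


@dataclass(frozen=True)
class VelocityParams:
    """Open-field-like velocity: a baseline speed plus Poisson locomotion bouts."""

    baseline_cm_s: float = 2.0
    bout_rate_hz: float = 0.02
    bout_peak_cm_s: float = 20.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of one synthetic recording session.

    Defaults describe a plausible rig: 60 frames/s combined (30/s per
    channel), photobleaching with a 600-s time constant over a constant
    offset, sparse sub-second motion artifacts shared between channels, and
    per-channel Gaussian sensor noise.
    """

    duration_s: float
    combined_rate: float = 60.0
    bleach_amplitude: float = 30.0
    bleach_tau_s: float = 600.0
    bleach_offset: float = 50.0
    transient_events: tuple[TransientEvent, ...] = ()
    step_events: tuple[StepEvent, ...] = ()
    artifact_rate_hz: float = 0.1
    artifact_amplitude_sd: float = 5.0
    artifact_channel_gain: float = 0.5
    noise_sd: float = 2.0
    behavior_schedule: tuple[tuple[str, float, float], ...] = ()
    velocity_params: VelocityParams = field(default_factory=VelocityParams)
    seed: int = 0

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise ValidationError("duration_s must be > 0")
        if self.combined_rate <= 0:
            raise ValidationError("combined_rate must be > 0")
        if self.bleach_tau_s <= 0:
            raise ValidationError("bleach_tau_s must be > 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.artifact_rate_hz < 0:
            raise ValidationError("artifact_rate_hz must be >= 0")
        if self.artifact_amplitude_sd < 0:
            raise ValidationError("artifact_amplitude_sd must be >= 0")
        if self.artifact_channel_gain < 0:
            raise ValidationError("artifact_channel_gain must be >= 0")
        for ev in self.transient_events:
            if not (0.0 <= ev.onset_s < self.duration_s):
                raise ValidationError(
                    f"transient_events onset {ev.onset_s} outside [0, duration_s)"
                )
            if ev.rise_tau_s <= 0 or ev.decay_tau_s <= 0:
                raise ValidationError("transient_events taus must be > 0")
        for ev in self.step_events:
            if not (0.0 <= ev.onset_s < self.duration_s):
                raise ValidationError(
                    f"step_events onset {ev.onset_s} outside [0, duration_s)"
                )
            if ev.duration_s <= 0:
                raise ValidationError("step_events duration_s must be > 0")
        _validate_schedule(self.behavior_schedule)


def _validate_schedule(schedule: Sequence[tuple[str, float, float]]) -> None:
    prev_end = None
    for state, start, end in schedule:
        if end <= start:
            raise ValidationError(
                f"behavior_schedule interval ({state!r}, {start}, {end}) is empty"
            )
        if prev_end is not None and start < prev_end - 1e-9:
            raise ValidationError("behavior_schedule intervals overlap or are unordered")
        prev_end = end


@dataclass
class GroundTruth:
    """Everything injected into a recording, for recovery testing."""

    transient_onsets: np.ndarray
    transient_amplitudes: np.ndarray
    step_intervals: list[tuple[float, float, float]]
    artifact_times: np.ndarray
    artifact_amplitudes: np.ndarray
    behavior_schedule: tuple[tuple[str, float, float], ...]
    seed: int


def transient_kernel(
    t: np.ndarray, rise_tau_s: float, decay_tau_s: float
) -> np.ndarray:
    """Fast-rise / slow-decay kernel, zero before t = 0, unit amplitude scale."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t >= 0
    tp = t[pos]
    out[pos] = (1.0 - np.exp(-tp / rise_tau_s)) * np.exp(-tp / decay_tau_s)
    return out


def kernel_peak_time(rise_tau_s: float, decay_tau_s: float) -> float:
    """Analytic maximum of the transient kernel: tau_r * ln(1 + tau_d/tau_r)."""
    return rise_tau_s * math.log(1.0 + decay_tau_s / rise_tau_s)


def kernel_peak_value(rise_tau_s: float, decay_tau_s: float) -> float:
    tpk = kernel_peak_time(rise_tau_s, decay_tau_s)
    return float(
        (1.0 - math.exp(-tpk / rise_tau_s)) * math.exp(-tpk / decay_tau_s)
    )


def _bleach(spec: SyntheticSpec, t: np.ndarray) -> np.ndarray:
    return spec.bleach_amplitude * np.exp(-t / spec.bleach_tau_s) + spec.bleach_offset


def _add_kernel_events(
    values: np.ndarray, t: np.ndarray, rate: float, events
) -> None:
    for ev in events:
        support = 10.0 * ev.decay_tau_s + 5.0 * ev.rise_tau_s
        i0 = int(np.searchsorted(t, ev.onset_s))
        i1 = min(int(np.searchsorted(t, ev.onset_s + support)) + 1, t.size)
        values[i0:i1] += ev.amplitude * transient_kernel(
            t[i0:i1] - ev.onset_s, ev.rise_tau_s, ev.decay_tau_s
        )


def generate_recording(
    spec: SyntheticSpec,
) -> tuple[PhotometryRecording, GroundTruth]:
    """Generate an interleaved two-channel recording plus its ground truth.

    Interleaving order is fixed as (isosbestic, calcium) repeating; the
    channel of every frame is recorded explicitly in the frame table. The
    Ca2+ channel is bleach + transients + steps + shared artifacts + noise;
    the isosbestic channel is its own bleach + gain-scaled copies of the same
    artifact realizations + independent noise, with no transient or step
    terms. Motion is slow relative to the 1/combined_rate gap between the two
    frames of a pair, so each artifact sample is evaluated once per pair and
    added to both frames.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    channel_rate = spec.combined_rate / 2.0
    n_pairs = int(round(spec.duration_s * channel_rate))
    if n_pairs < 1:
        raise ValidationError("duration_s too short for a single frame pair")
    iso_t = (2.0 * np.arange(n_pairs)) / spec.combined_rate
    ca_t = (2.0 * np.arange(n_pairs) + 1.0) / spec.combined_rate

    ca = _bleach(spec, ca_t)
    iso = _bleach(spec, iso_t)

    _add_kernel_events(ca, ca_t, channel_rate, spec.transient_events)
    for ev in spec.step_events:
        mask = (ca_t >= ev.onset_s) & (ca_t < ev.onset_s + ev.duration_s)
        ca[mask] += ev.magnitude

    n_art = rng.poisson(spec.artifact_rate_hz * spec.duration_s)
    art_times = np.sort(rng.uniform(0.0, spec.duration_s, n_art))
    art_amps = rng.normal(0.0, spec.artifact_amplitude_sd, n_art)
    if n_art:
        shared = np.zeros(n_pairs)
        pair_t = iso_t  # one artifact sample per frame pair
        for t0, a in zip(art_times, art_amps):
            support = 10.0 * ARTIFACT_DECAY_TAU_S
            i0 = int(np.searchsorted(pair_t, t0))
            i1 = min(int(np.searchsorted(pair_t, t0 + support)) + 1, n_pairs)
            shared[i0:i1] += a * transient_kernel(
                pair_t[i0:i1] - t0, ARTIFACT_RISE_TAU_S, ARTIFACT_DECAY_TAU_S
            )
        ca += shared
        iso += spec.artifact_channel_gain * shared

    if spec.noise_sd > 0:
        iso += rng.normal(0.0, spec.noise_sd, n_pairs)
        ca += rng.normal(0.0, spec.noise_sd, n_pairs)

    values = np.empty(2 * n_pairs)
    values[0::2] = iso
    values[1::2] = ca
    channels = np.empty(2 * n_pairs, dtype=object)
    channels[0::2] = CHANNEL_ISO
    channels[1::2] = CHANNEL_CA
    frames = pd.DataFrame(
        {
            "frame": np.arange(2 * n_pairs),
            "system_time_s": np.arange(2 * n_pairs) / spec.combined_rate,
            "channel": channels,
            "value": values,
        }
    )
    recording = PhotometryRecording(frames, combined_rate=spec.combined_rate)
    truth = GroundTruth(
        transient_onsets=np.array([e.onset_s for e in spec.transient_events]),
        transient_amplitudes=np.array([e.amplitude for e in spec.transient_events]),
        step_intervals=[
            (e.onset_s, e.onset_s + e.duration_s, e.magnitude)
            for e in spec.step_events
        ],
        artifact_times=art_times,
        artifact_amplitudes=art_amps,
        behavior_schedule=spec.behavior_schedule,
        seed=spec.seed,
    )
    return recording, truth


def generate_behavior_track(
    schedule: Sequence[tuple[str, float, float]],
    frame_rate: float,
    categories: Sequence[str],
) -> BehaviorTrack:
    """Per-frame labels from a (state, start_s, end_s) schedule.

    The schedule must tile [0, duration) without gaps or overlaps; frame i
    (at time i / frame_rate) takes the label of the interval containing it.
    """
    if not categories:
        raise ValidationError("categories must be a non-empty label set")
    if not schedule:
        raise ValidationError("schedule must contain at least one interval")
    _validate_schedule(schedule)
    if abs(schedule[0][1]) > 1e-9:
        raise ValidationError("schedule must start at 0")
    for (_, _, end), (_, start, _) in zip(schedule, schedule[1:]):
        if abs(start - end) > 1e-9:
            raise ValidationError(f"schedule has a gap at t={end}")
    cat_set = set(categories)
    for state, _, _ in schedule:
        if state not in cat_set:
            raise ValidationError(f"schedule state {state!r} not in categories")
    duration = schedule[-1][2]
    n_frames = int(round(duration * frame_rate))
    ends = np.array([end for _, _, end in schedule])
    states = [state for state, _, _ in schedule]
    t = np.arange(n_frames) / frame_rate
    idx = np.searchsorted(ends, t, side="right")
    idx = np.clip(idx, 0, len(states) - 1)
    labels = np.array([states[i] for i in idx], dtype=object)
    return BehaviorTrack(labels, frame_rate, tuple(categories))


def generate_velocity(
    params: VelocityParams,
    duration_s: float,
    sample_rate: float,
    seed: int = 0,
    bout_width_s: float = 1.0,
    jitter_sd_cm_s: float = 0.5,
) -> tuple[VelocityTrace, EventSet]:
    """Velocity trace with Poisson-timed Gaussian locomotion bouts.

    Returns the trace and the true bout-center events (for gating oracles).
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate))
    t = np.arange(n) / sample_rate
    v = np.full(n, params.baseline_cm_s)
    n_bouts = rng.poisson(params.bout_rate_hz * duration_s)
    centers = np.sort(rng.uniform(0.0, duration_s, n_bouts))
    peak = max(params.bout_peak_cm_s - params.baseline_cm_s, 0.0)
    for c in centers:
        v += peak * np.exp(-0.5 * ((t - c) / bout_width_s) ** 2)
    if jitter_sd_cm_s > 0:
        v += rng.normal(0.0, jitter_sd_cm_s, n)
    trace = VelocityTrace(t, np.maximum(v, 0.0), sample_rate, source="provided")
    return trace, EventSet.from_onsets(centers, label="bout")


def generate_operant_events(
    agent_rate_active: float,
    agent_rate_inactive: float,
    duration_s: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Poisson nose-poke streams per port, merged and time-sorted.

    Models an indifferent agent poking each port at a constant rate; the
    schedule logic downstream decides what the pokes earn.
    """
    if agent_rate_active < 0 or agent_rate_inactive < 0:
        raise ValidationError("port event rates must be >= 0")
    if duration_s <= 0:
        raise ValidationError("duration_s must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    for port, rate in (("active", agent_rate_active), ("inactive", agent_rate_inactive)):
        n = rng.poisson(rate * duration_s)
        for ts in np.sort(rng.uniform(0.0, duration_s, n)):
            rows.append((float(ts), port))
    rows.sort(key=lambda r: r[0])
    return pd.DataFrame(rows, columns=["time_s", "port"])


def baseline_sd_smoothed(spec: SyntheticSpec, smooth_window: int) -> float:
    """Analytic SD of the smoothed event-free (baseline) signal.

    Two contributions: white sensor noise attenuated by the moving average
    (noise_sd / sqrt(w)), and artifact shot noise via Campbell's theorem
    (rate * amp_sd^2 * integral of the smoothed kernel squared), evaluated on
    the per-channel sample grid. Used to express injected amplitudes in
    baseline-SD ("z") units.
    """
    channel_rate = spec.combined_rate / 2.0
    dt = 1.0 / channel_rate
    var = spec.noise_sd**2 / smooth_window
    if spec.artifact_rate_hz > 0 and spec.artifact_amplitude_sd > 0:
        support = 10.0 * ARTIFACT_DECAY_TAU_S + smooth_window * dt
        tk = np.arange(0.0, support, dt)
        k = transient_kernel(tk, ARTIFACT_RISE_TAU_S, ARTIFACT_DECAY_TAU_S)
        box = np.ones(smooth_window) / smooth_window
        k_sm = np.convolve(k, box, mode="full")
        var += (
            spec.artifact_rate_hz
            * spec.artifact_amplitude_sd**2
            * float(np.sum(k_sm**2))
            * dt
        )
    return float(np.sqrt(var))


def dunk_protocol(
    n_trials: int = 10,
    trial_s: float = 30.0,
    interval_s: float = 120.0,
    lead_in_s: float = 60.0,
    amplitude_z: float = 5.0,
    smooth_window: int = 9,
    seed: int = 0,
    **overrides,
) -> tuple[SyntheticSpec, EventSet]:
    """Repeated forced-swim (dunk) session: sustained steps every 2 minutes.

    Each trial is a rectangular Ca2+ elevation lasting ``trial_s`` (rapid
    rise at platform lowering, sustained through the swim, return at platform
    raise). ``amplitude_z`` is expressed in units of the smoothed baseline SD
    (see :func:`baseline_sd_smoothed`), mirroring how event-locked rises are
    read off a standardized trace against its baseline variability.
    """
    duration = lead_in_s + (n_trials - 1) * interval_s + trial_s + lead_in_s
    base = SyntheticSpec(duration_s=duration, seed=seed, **overrides)
    amp = amplitude_z * baseline_sd_smoothed(base, smooth_window)
    onsets = [lead_in_s + i * interval_s for i in range(n_trials)]
    steps = tuple(StepEvent(t0, amp, trial_s) for t0 in onsets)
    spec = replace(base, step_events=steps)
    return spec, EventSet.from_onsets(onsets, duration_s=trial_s, label="dunk")


def shock_protocol(
    n_trials: int = 5,
    interval_s: float = 90.0,
    lead_in_s: float = 60.0,
    amplitude_z: float = 5.0,
    rise_tau_s: float = 0.5,
    decay_tau_s: float = 3.0,
    smooth_window: int = 9,
    seed: int = 0,
    **overrides,
) -> tuple[SyntheticSpec, EventSet]:
    """Foot-shock-like session: brief high-amplitude transients.

    ``amplitude_z`` sets the kernel's *peak* in smoothed-baseline-SD units.
    """
    duration = lead_in_s + (n_trials - 1) * interval_s + lead_in_s
    base = SyntheticSpec(duration_s=duration, seed=seed, **overrides)
    peak = kernel_peak_value(rise_tau_s, decay_tau_s)
    amp = amplitude_z * baseline_sd_smoothed(base, smooth_window) / peak
    onsets = [lead_in_s + i * interval_s for i in range(n_trials)]
    transients = tuple(
        TransientEvent(t0, amp, rise_tau_s, decay_tau_s) for t0 in onsets
    )
    spec = replace(base, transient_events=transients)
    return spec, EventSet.from_onsets(onsets, duration_s=2.0, label="shock")


def feeding_protocol(
    baseline_s: float = 300.0,
    post_s: float = 900.0,
    drop_z: float = 3.0,
    smooth_window: int = 9,
    seed: int = 0,
    **overrides,
) -> tuple[SyntheticSpec, EventSet]:
    """Feeding-suppression session: one sustained step drop after baseline.

    The drop persists to the end of the recording; its nature and duration
    defeat exponential baseline fitting, so these sessions are analyzed in
    reference-window z-score mode (5 min of baseline, then scored against the
    baseline state's variability). Bleaching is weak by default — the
    sustained drop, not bleaching, dominates these sessions, and reference
    z-scoring does not remove a bleach trend.
    """
    duration = baseline_s + post_s
    overrides.setdefault("bleach_amplitude", 1.0)
    overrides.setdefault("bleach_tau_s", 1800.0)
    base = SyntheticSpec(duration_s=duration, seed=seed, **overrides)
    drop = drop_z * baseline_sd_smoothed(base, smooth_window)
    spec = replace(
        base, step_events=(StepEvent(baseline_s, -drop, post_s),)
    )
    return spec, EventSet.from_onsets([baseline_s], duration_s=post_s, label="food")
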