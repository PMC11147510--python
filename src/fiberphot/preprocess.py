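"""Photometry signal chain: raw interleaved frames to z-scored dF/F.

A two-channel recording interleaves an isosbestic (~415 nm excitation,
Ca2+-insensitive) and a Ca2+-dependent (~470 nm, GCaMP) channel at a combined
rate of 60 frames/s (30 frames/s per channel). The default chain is

    deinterleave -> moving-average smooth -> exponential photobleaching
    detrend (per channel) -> z-score (full trace, population SD) ->
    non-negative robust scaling of the isosbestic onto the Ca2+ channel ->
    dF/F = ca_z - iso_fitted

The scaled isosbestic predicts the motion/artifact component shared by both
channels; subtracting it leaves the Ca2+-specific signal. Recordings with a
sustained step change (e.g. feeding-type suppression) defeat the exponential
baseline model; for those the chain falls back to reference-window z-scoring
of both channels with no baseline correction (``reference_z`` mode).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import (
    BaselineFitError,
    PipelineError,
    RecordingCorruptionError,
    ValidationError,
    ZeroVarianceError,
)

__all__ = [
    "CHANNEL_ISO",
    "CHANNEL_CA",
    "PhotometryRecording",
    "TraceSeries",
    "BaselineFit",
    "ScalingFit",
    "PreprocessConfig",
    "ProcessedTrace",
    "deinterleave",
    "interleave",
    "smooth_moving_average",
    "fit_exponential_baseline",
    "standardize",
    "scale_isosbestic",
    "compute_dff",
    "zscore_reference",
    "preprocess",
]

CHANNEL_ISO = "isosbestic_415"
CHANNEL_CA = "calcium_470"


@dataclass
class PhotometryRecording:
    """Raw interleaved two-channel recording.

    ``frames`` has columns ``frame`` (index), ``system_time_s``, ``channel``
    (one of :data:`CHANNEL_ISO`, :data:`CHANNEL_CA`) and ``value``
    (fluorescence, arbitrary units). Channels must strictly alternate and
    time must strictly increase.
    """

    frames: pd.DataFrame
    combined_rate: float

    def __post_init__(self) -> None:
        required = {"frame", "system_time_s", "channel", "value"}
        missing = required - set(self.frames.columns)
        if missing:
            raise ValidationError(f"frames missing columns: {sorted(missing)}")
        if self.combined_rate <= 0:
            raise ValidationError("combined_rate must be > 0")
        ch = self.frames["channel"].to_numpy()
        bad = set(pd.unique(ch)) - {CHANNEL_ISO, CHANNEL_CA}
        if bad:
            raise ValidationError(f"unknown channel labels: {sorted(bad)}")
        t = self.frames["system_time_s"].to_numpy(dtype=float)
        if t.size > 1 and np.any(np.diff(t) <= 0):
            i = int(np.flatnonzero(np.diff(t) <= 0)[0])
            raise ValidationError(f"time not strictly increasing at frame {i + 1}")

    @property
    def channel_rate(self) -> float:
        return self.combined_rate / 2.0

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class TraceSeries:
    """Uniformly sampled single-channel series."""

    time_s: np.ndarray
    values: np.ndarray
    rate: float
    channel: str = ""

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.time_s.shape != self.values.shape:
            raise ValidationError("time_s and values must have equal length")

    def __len__(self) -> int:
        return self.values.size


def deinterleave(recording: PhotometryRecording) -> tuple[TraceSeries, TraceSeries]:
    """Split an interleaved recording into (isosbestic, calcium) series.

    Raises :class:`RecordingCorruptionError` (naming the frame index) if two
    consecutive frames carry the same channel.
    """
    ch = recording.frames["channel"].to_numpy()
    if ch.size > 1:
        same = np.flatnonzero(ch[1:] == ch[:-1])
        if same.size:
            i = int(same[0])
            raise RecordingCorruptionError(
                f"frames {i} and {i + 1} both carry channel {ch[i]!r}; "
                "channels must strictly alternate"
            )
    t = recording.frames["system_time_s"].to_numpy(dtype=float)
    v = recording.frames["value"].to_numpy(dtype=float)
    out = []
    for name in (CHANNEL_ISO, CHANNEL_CA):
        mask = ch == name
        out.append(
            TraceSeries(t[mask], v[mask], rate=recording.channel_rate, channel=name)
        )
    return out[0], out[1]


def interleave(
    iso: TraceSeries, ca: TraceSeries, combined_rate: float | None = None
) -> PhotometryRecording:
    """Re-interleave two channel series by time (round-trip of deinterleave)."""
    rate = combined_rate if combined_rate is not None else 2.0 * iso.rate
    t = np.concatenate([iso.time_s, ca.time_s])
    v = np.concatenate([iso.values, ca.values])
    c = np.array([CHANNEL_ISO] * len(iso) + [CHANNEL_CA] * len(ca), dtype=object)
    order = np.argsort(t, kind="stable")
    frames = pd.DataFrame(
        {
            "frame": np.arange(t.size),
            "system_time_s": t[order],
            "channel": c[order],
            "value": v[order],
        }
    )
    return PhotometryRecording(frames, combined_rate=rate)


def smooth_moving_average(values: np.ndarray, window_samples: int) -> np.ndarray:
    """Centered moving mean with shrinking (truncated) windows at the edges.

    ``window_samples`` must be an odd positive integer no larger than the
    series length. Output length equals input length; no samples are invented
    at the edges — the window simply shrinks to what is available.
    """
    x = np.asarray(values, dtype=float)
    w = int(window_samples)
    if w < 1 or w % 2 == 0:
        raise ValidationError("window_samples must be an odd positive integer")
    if w > x.size:
        raise ValidationError(
            f"window_samples={w} exceeds series length {x.size}"
        )
    if w == 1:
        return x.copy()
    half = w // 2
    csum = np.concatenate([[0.0], np.cumsum(x)])
    idx = np.arange(x.size)
    lo = np.clip(idx - half, 0, x.size)
    hi = np.clip(idx + half + 1, 0, x.size)
    return (csum[hi] - csum[lo]) / (hi - lo)


@dataclass(frozen=True)
class BaselineFit:
    """Parameters of the photobleaching model b0 * exp(-t / tau) + b1."""

    amplitude: float
    tau_s: float
    offset: float
    r_squared: float
    converged: bool

    def evaluate(self, time_s: np.ndarray) -> np.ndarray:
        t = np.asarray(time_s, dtype=float)
        return self.amplitude * np.exp(-t / self.tau_s) + self.offset


def _exp_model(t, b0, tau, b1):
    return b0 * np.exp(-t / tau) + b1


def _exp_jac(t, b0, tau, b1):
    e = np.exp(-t / tau)
    return np.column_stack([e, b0 * t * e / tau**2, np.ones_like(t)])


def fit_exponential_baseline(
    values: np.ndarray, time_s: np.ndarray, max_nfev: int = 2000
) -> tuple[BaselineFit, np.ndarray]:
    """Fit a single-exponential photobleaching baseline by nonlinear LSQ.

    The fit is initialized log-linearly (head/tail means give amplitude and
    offset; the decay constant starts at a third of the span). Returns the
    fit (with an R^2 diagnostic) and the detrended series. Raises
    :class:`BaselineFitError` if the optimizer does not converge; callers may
    then fall back to reference-window z-scoring.
    """
    y = np.asarray(values, dtype=float)
    t = np.asarray(time_s, dtype=float)
    if y.size < 10:
        raise ValidationError("need at least 10 samples to fit a baseline")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(t))):
        raise ValidationError("baseline fit requires finite values and times")
    t0 = t - t[0]
    scale = max(1.0, float(np.max(np.abs(y))))
    if np.std(y) < 1e-12 * scale:
        # Degenerate: a constant series is the exponential with zero amplitude.
        fit = BaselineFit(0.0, max(t0[-1], 1.0), float(np.mean(y)), 1.0, True)
        return fit, y - fit.offset

    k = max(1, y.size // 10)
    head = float(np.mean(y[:k]))
    tail = float(np.mean(y[-k:]))
    b1_0 = tail
    b0_0 = head - tail if head != tail else float(np.std(y))
    tau_0 = max(t0[-1] / 3.0, 1e-3)
    try:
        popt, _ = curve_fit(
            _exp_model,
            t0,
            y,
            p0=[b0_0, tau_0, b1_0],
            jac=_exp_jac,
            bounds=([-np.inf, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
            max_nfev=max_nfev,
        )
    except (RuntimeError, ValueError) as exc:
        raise BaselineFitError(f"exponential baseline fit failed: {exc}") from exc
    fitted = _exp_model(t0, *popt)
    resid = y - fitted
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    fit = BaselineFit(float(popt[0]), float(popt[1]), float(popt[2]), r2, True)
    return fit, resid


def standardize(values: np.ndarray) -> np.ndarray:
    """Z-score over the full series using the population (n) SD convention."""
    x = np.asarray(values, dtype=float)
    sd = float(np.std(x))
    if sd == 0.0:
        raise ZeroVarianceError("cannot standardize a zero-variance series")
    return (x - float(np.mean(x))) / sd


@dataclass(frozen=True)
class ScalingFit:
    """Non-negative robust scaling of the isosbestic onto the Ca2+ channel."""

    slope: float
    intercept: float
    clamped: bool

    def evaluate(self, iso_z: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(iso_z, dtype=float) + self.intercept


_HUBER_T = 1.345
_MAD_C = 0.6744897501960817  # Phi^{-1}(0.75): MAD -> sigma for a normal


def _huber_irls(
    x: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-10
) -> tuple[float, float]:
    """Huber-loss line fit (intercept, slope) by IRLS with MAD scale.

    Standard iteratively-reweighted least squares: residual scale is the
    (normal-consistent) median absolute deviation, weights are 1 inside
    ``_HUBER_T`` scaled residuals and ``t/|u|`` outside. The two-parameter
    weighted solve is closed form, so each iteration is O(n).
    """
    # OLS start
    slope = float(np.cov(x, y, bias=True)[0, 1] / np.var(x)) if np.var(x) > 0 else 0.0
    intercept = float(np.mean(y) - slope * np.mean(x))
    for _ in range(max_iter):
        r = y - intercept - slope * x
        scale = float(np.median(np.abs(r))) / _MAD_C
        if scale <= 0:
            break
        u = np.abs(r) / scale
        w = np.where(u <= _HUBER_T, 1.0, _HUBER_T / np.maximum(u, 1e-300))
        sw = w.sum()
        swx = float(w @ x)
        swy = float(w @ y)
        swxx = float(w @ (x * x))
        swxy = float(w @ (x * y))
        denom = sw * swxx - swx * swx
        if denom <= 0:
            break
        new_slope = (sw * swxy - swx * swy) / denom
        new_intercept = (swy - new_slope * swx) / sw
        if (
            abs(new_slope - slope) < tol * max(1.0, abs(slope))
            and abs(new_intercept - intercept) < tol * max(1.0, abs(intercept))
        ):
            slope, intercept = new_slope, new_intercept
            break
        slope, intercept = new_slope, new_intercept
    return intercept, slope


def _huber_location(x: np.ndarray, max_iter: int = 100, tol: float = 1e-10) -> float:
    loc = float(np.median(x))
    for _ in range(max_iter):
        r = x - loc
        scale = float(np.median(np.abs(r))) / _MAD_C
        if scale <= 0:
            break
        u = np.abs(r) / scale
        w = np.where(u <= _HUBER_T, 1.0, _HUBER_T / np.maximum(u, 1e-300))
        new_loc = float((w @ x) / w.sum())
        if abs(new_loc - loc) < tol * max(1.0, abs(loc)):
            return new_loc
        loc = new_loc
    return loc


def scale_isosbestic(
    iso_z: np.ndarray, ca_z: np.ndarray
) -> tuple[ScalingFit, np.ndarray]:
    """Robustly regress the Ca2+ channel on the isosbestic, slope >= 0.

    Huber-loss (tuning constant 1.345, MAD scale) linear regression of
    ``ca_z`` on ``iso_z``. If the unconstrained slope is negative it is
    clamped to zero and the intercept refit as the Huber location of
    ``ca_z`` — the two procedures agree whenever the constraint is inactive.
    Returns the fit and ``iso_fitted = slope * iso_z + intercept``.
    """
    x = np.asarray(iso_z, dtype=float)
    y = np.asarray(ca_z, dtype=float)
    if x.size != y.size:
        raise ValidationError(f"length mismatch: iso {x.size} vs ca {y.size}")
    if x.size < 10:
        raise ValidationError("need at least 10 samples for robust scaling")
    intercept, slope = _huber_irls(x, y)
    clamped = False
    if slope < 0.0:
        slope = 0.0
        intercept = _huber_location(y)
        clamped = True
    fit = ScalingFit(slope=slope, intercept=intercept, clamped=clamped)
    return fit, fit.evaluate(x)


def compute_dff(
    ca_z: np.ndarray,
    iso_fitted: np.ndarray,
    method: Literal["subtract", "divide"] = "subtract",
) -> np.ndarray:
    """Motion-corrected normalized signal.

    Default is subtraction in standardized space, ``ca_z - iso_fitted``,
    i.e. the Ca2+ channel minus the scaled isosbestic prediction of shared
    motion/artifact. A division form ``(ca_z - iso_fitted) / iso_fitted`` is
    available but off by default: in standardized space the denominator can
    pass near zero, in which case it raises.
    """
    ca = np.asarray(ca_z, dtype=float)
    iso = np.asarray(iso_fitted, dtype=float)
    if ca.size != iso.size:
        raise ValidationError(f"length mismatch: ca {ca.size} vs iso {iso.size}")
    if method == "subtract":
        return ca - iso
    if method == "divide":
        if np.min(np.abs(iso)) < 1e-6:
            raise ValidationError(
                "division-based dF/F undefined: scaled isosbestic passes near zero"
            )
        return (ca - iso) / iso
    raise ValidationError(f"unknown dF/F method {method!r}")


def zscore_reference(
    values: np.ndarray,
    time_s: np.ndarray,
    reference_window: tuple[float, float],
) -> np.ndarray:
    """Z-score against the mean/SD of a reference window only.

    Used for recordings whose sustained step change precludes baseline
    fitting: both channels are scored against their own baseline-state
    variability and shown side by side.
    """
    x = np.asarray(values, dtype=float)
    t = np.asarray(time_s, dtype=float)
    a, b = reference_window
    if not b > a:
        raise ValidationError(f"degenerate reference window {reference_window}")
    mask = (t >= a) & (t < b)
    if not mask.any():
        raise ValidationError(f"reference window {reference_window} is empty")
    ref = x[mask]
    sd = float(np.std(ref))
    if sd == 0.0:
        raise ZeroVarianceError("reference window has zero variance")
    return (x - float(np.mean(ref))) / sd


@dataclass(frozen=True)
class PreprocessConfig:
    """Options for the full signal chain.

    mode
        ``"baseline"`` — exponential detrend, full-trace z-score, isosbestic
        scaling and dF/F (with automatic fallback to reference mode when the
        Ca2+ baseline fit fails or its R^2 falls below ``fallback_r2``);
        ``"reference"`` — reference-window z-scoring of both channels, no
        baseline correction.
    smooth_window
        Moving-average width in samples (odd; 9 samples ~ 0.3 s at 30/s).
    reference_window
        (start_s, end_s) of the baseline state; defaults to the first quarter
        of the recording when needed.
    """

    mode: Literal["baseline", "reference"] = "baseline"
    smooth_window: int = 9
    reference_window: tuple[float, float] | None = None
    dff_method: Literal["subtract", "divide"] = "subtract"
    fallback_r2: float = 0.5
    allow_fallback: bool = True
    smooth_first: bool = True


@dataclass
class ProcessedTrace:
    """All stages of the signal chain for one recording."""

    time_s: np.ndarray
    ca_raw: np.ndarray
    iso_raw: np.ndarray
    ca_smoothed: np.ndarray
    iso_smoothed: np.ndarray
    mode: Literal["baseline_corrected", "reference_z"]
    sample_rate: float
    ca_z: np.ndarray
    iso_z: np.ndarray
    ca_detrended: np.ndarray | None = None
    iso_detrended: np.ndarray | None = None
    iso_fitted: np.ndarray | None = None
    dff: np.ndarray | None = None
    baseline_params: dict[str, BaselineFit] | None = None
    scaling: ScalingFit | None = None
    standardization: dict[str, tuple[float, float]] | None = None
    fallback_reason: str | None = None
    config: PreprocessConfig = field(default_factory=PreprocessConfig)

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per sample, one column per stage."""
        cols = {
            "time_s": self.time_s,
            "ca_raw": self.ca_raw,
            "iso_raw": self.iso_raw,
            "ca_smoothed": self.ca_smoothed,
            "iso_smoothed": self.iso_smoothed,
            "ca_z": self.ca_z,
            "iso_z": self.iso_z,
        }
        for name, arr in (
            ("ca_detrended", self.ca_detrended),
            ("iso_detrended", self.iso_detrended),
            ("iso_fitted", self.iso_fitted),
            ("dff", self.dff),
        ):
            if arr is not None:
                cols[name] = arr
        return pd.DataFrame(cols)


def _default_reference_window(time_s: np.ndarray) -> tuple[float, float]:
    span = float(time_s[-1] - time_s[0])
    return (float(time_s[0]), float(time_s[0]) + 0.25 * span)


def preprocess(
    recording: PhotometryRecording, config: PreprocessConfig | None = None
) -> ProcessedTrace:
    """Run the full signal chain on an interleaved recording."""
    cfg = config or PreprocessConfig()
    try:
        iso, ca = deinterleave(recording)
    except RecordingCorruptionError as exc:
        raise PipelineError(f"deinterleave: {exc}") from exc

    n = min(len(iso), len(ca))
    iso_v, ca_v = iso.values[:n], ca.values[:n]
    # The shared time base is the Ca channel's sample times (second of each pair).
    time_s = ca.time_s[:n]

    try:
        iso_sm = smooth_moving_average(iso_v, cfg.smooth_window)
        ca_sm = smooth_moving_average(ca_v, cfg.smooth_window)
    except ValidationError as exc:
        raise PipelineError(f"smooth: {exc}") from exc

    if cfg.mode == "reference":
        return _reference_branch(
            cfg, time_s, ca_v, iso_v, ca_sm, iso_sm, recording.channel_rate, None
        )
    if cfg.mode != "baseline":
        raise ValidationError(f"unknown mode {cfg.mode!r}")

    ca_in = ca_sm if cfg.smooth_first else ca_v
    iso_in = iso_sm if cfg.smooth_first else iso_v
    fallback_reason = None
    try:
        ca_fit, ca_det = fit_exponential_baseline(ca_in, time_s)
        iso_fit, iso_det = fit_exponential_baseline(iso_in, time_s)
        worst_r2 = min(ca_fit.r_squared, iso_fit.r_squared)
        if worst_r2 < cfg.fallback_r2:
            fallback_reason = (
                f"baseline fit R^2 {worst_r2:.3f} below threshold {cfg.fallback_r2}"
            )
    except BaselineFitError as exc:
        fallback_reason = str(exc)

    if fallback_reason is not None:
        if not cfg.allow_fallback:
            raise PipelineError(f"baseline fit: {fallback_reason}")
        return _reference_branch(
            cfg,
            time_s,
            ca_v,
            iso_v,
            ca_sm,
            iso_sm,
            recording.channel_rate,
            fallback_reason,
        )

    if not cfg.smooth_first:
        ca_det = smooth_moving_average(ca_det, cfg.smooth_window)
        iso_det = smooth_moving_average(iso_det, cfg.smooth_window)
    try:
        ca_z = standardize(ca_det)
        iso_z = standardize(iso_det)
    except ZeroVarianceError as exc:
        raise PipelineError(f"standardize: {exc}") from exc
    scaling, iso_fitted = scale_isosbestic(iso_z, ca_z)
    dff = compute_dff(ca_z, iso_fitted, method=cfg.dff_method)
    return ProcessedTrace(
        time_s=time_s,
        ca_raw=ca_v,
        iso_raw=iso_v,
        ca_smoothed=ca_sm,
        iso_smoothed=iso_sm,
        ca_detrended=ca_det,
        iso_detrended=iso_det,
        ca_z=ca_z,
        iso_z=iso_z,
        iso_fitted=iso_fitted,
        dff=dff,
        mode="baseline_corrected",
        sample_rate=recording.channel_rate,
        baseline_params={CHANNEL_CA: ca_fit, CHANNEL_ISO: iso_fit},
        scaling=scaling,
        standardization={
            CHANNEL_CA: (float(np.mean(ca_det)), float(np.std(ca_det))),
            CHANNEL_ISO: (float(np.mean(iso_det)), float(np.std(iso_det))),
        },
        config=cfg,
    )


def _reference_branch(
    cfg: PreprocessConfig,
    time_s: np.ndarray,
    ca_v: np.ndarray,
    iso_v: np.ndarray,
    ca_sm: np.ndarray,
    iso_sm: np.ndarray,
    rate: float,
    fallback_reason: str | None,
) -> ProcessedTrace:
    window = cfg.reference_window or _default_reference_window(time_s)
    try:
        ca_z = zscore_reference(ca_sm, time_s, window)
        iso_z = zscore_reference(iso_sm, time_s, window)
    except (ValidationError, ZeroVarianceError) as exc:
        raise PipelineError(f"reference z-score: {exc}") from exc
    mask = (time_s >= window[0]) & (time_s < window[1])
    return ProcessedTrace(
        time_s=time_s,
        ca_raw=ca_v,
        iso_raw=iso_v,
        ca_smoothed=ca_sm,
        iso_smoothed=iso_sm,
        ca_z=ca_z,
        iso_z=iso_z,
        mode="reference_z",
        sample_rate=rate,
        standardization={
            CHANNEL_CA: (float(np.mean(ca_sm[mask])), float(np.std(ca_sm[mask]))),
            CHANNEL_ISO: (float(np.mean(iso_sm[mask])), float(np.std(iso_sm[mask]))),
        },
        fallback_reason=fallback_reason,
        config=replace(cfg, reference_window=window),
    )
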