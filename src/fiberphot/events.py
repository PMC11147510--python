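"""Peri-event alignment and windowed confidence-interval statistics.

Repeated events (dunk onsets, shocks, behavioral transitions, random control
epochs) are aligned into a trials x samples matrix of the processed signal.
Significance of an event-locked change is assessed the way it is conventionally
reported for photometry traces: per-trial window means are computed before and
after the point of interest, and a t-based confidence interval of the paired
differences is formed at the 95/99/99.9% levels; the change is called
significant at the highest level whose interval excludes zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError

__all__ = [
    "Event",
    "EventSet",
    "PeriEventMatrix",
    "CIResult",
    "CITestResult",
    "build_peri_event_matrix",
    "summarize_peri_event",
    "windowed_ci_test",
    "wilcoxon_window_test",
    "random_epoch_null",
    "significance_stars",
]


@dataclass(frozen=True)
class Event:
    """A labeled event; ``duration_s`` is optional (None for point events)."""

    onset_s: float
    duration_s: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.duration_s is not None and self.duration_s < 0:
            raise ValidationError(f"duration_s must be >= 0, got {self.duration_s}")


@dataclass
class EventSet:
    """Ordered collection of events."""

    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        onsets = [e.onset_s for e in self.events]
        if any(b < a for a, b in zip(onsets, onsets[1:])):
            raise ValidationError("event onsets must be sorted ascending")

    @classmethod
    def from_onsets(
        cls,
        onsets: Iterable[float],
        duration_s: float | None = None,
        label: str = "",
    ) -> "EventSet":
        return cls([Event(float(t), duration_s, label) for t in sorted(onsets)])

    @property
    def onsets(self) -> np.ndarray:
        return np.array([e.onset_s for e in self.events], dtype=float)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)


@dataclass
class PeriEventMatrix:
    """Trials x samples matrix of a signal aligned to event onsets.

    Row i is the signal over ``[onset_i - pre_s, onset_i + post_s)``; the
    relative time of column j is ``-pre_s + j / sample_rate``.
    """

    matrix: np.ndarray
    pre_s: float
    post_s: float
    sample_rate: float
    event_labels: list[str]
    excluded_events: list[tuple[Event, str]] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return self.matrix.shape[0]

    @property
    def time_s(self) -> np.ndarray:
        """Relative time axis (s); 0 is the event onset."""
        return -self.pre_s + np.arange(self.matrix.shape[1]) / self.sample_rate

    def window_columns(self, window: tuple[float, float]) -> np.ndarray:
        a, b = window
        if not b > a:
            raise ValidationError(f"degenerate window {window}")
        t = self.time_s
        mask = (t >= a) & (t < b)
        if not mask.any():
            raise ValidationError(f"window {window} contains no samples")
        return mask


@dataclass(frozen=True)
class CIResult:
    level: float
    lower: float
    upper: float
    significant: bool


@dataclass
class CITestResult:
    """Result of the windowed confidence-interval test.

    ``levels`` maps a confidence level in percent (e.g. 99.9) to its interval
    for the mean paired pre->post difference. Intervals nest by construction,
    so significance is monotone: significant at L implies significant at every
    lower level.
    """

    levels: dict[float, CIResult]
    window_means_pre: np.ndarray
    window_means_post: np.ndarray
    diffs: np.ndarray
    n: int

    @property
    def highest_significant_level(self) -> float | None:
        sig = [lvl for lvl, r in self.levels.items() if r.significant]
        return max(sig) if sig else None


_STAR_LEVELS = ((99.9, "***"), (99.0, "**"), (95.0, "*"))


def significance_stars(result: CITestResult) -> str:
    """Annotation string for the highest significant level (ns if none)."""
    lvl = result.highest_significant_level
    if lvl is None:
        return "ns"
    for thresh, stars in _STAR_LEVELS:
        if lvl >= thresh:
            return stars
    return "*"


def build_peri_event_matrix(
    trace_values: np.ndarray,
    sample_rate: float,
    events: EventSet,
    pre_s: float,
    post_s: float,
) -> PeriEventMatrix:
    """Align a signal to event onsets.

    Events whose window would run past either end of the recording are
    excluded and listed with a reason, so included rows + exclusions always
    account for every event.
    """
    values = np.asarray(trace_values, dtype=float)
    if pre_s <= 0 or post_s <= 0:
        raise ValidationError("pre_s and post_s must both be > 0")
    n_cols = int(round((pre_s + post_s) * sample_rate))
    rows: list[np.ndarray] = []
    labels: list[str] = []
    excluded: list[tuple[Event, str]] = []
    for ev in events:
        i0 = int(round((ev.onset_s - pre_s) * sample_rate))
        i1 = i0 + n_cols
        if i0 < 0:
            excluded.append((ev, "window underflow"))
        elif i1 > values.size:
            excluded.append((ev, "window overflow"))
        else:
            rows.append(values[i0:i1])
            labels.append(ev.label)
    if not rows:
        raise ValidationError("no events have a full window inside the recording")
    return PeriEventMatrix(
        matrix=np.vstack(rows),
        pre_s=pre_s,
        post_s=post_s,
        sample_rate=sample_rate,
        event_labels=labels,
        excluded_events=excluded,
    )


def _t_interval(d: np.ndarray, level: float) -> tuple[float, float]:
    n = d.size
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    alpha = 1.0 - level / 100.0
    half = stats.t.ppf(1.0 - alpha / 2.0, n - 1) * sd / np.sqrt(n)
    return mean - half, mean + half


def summarize_peri_event(
    matrix: PeriEventMatrix, level: float = 95.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-column mean and t-based confidence band across trials."""
    m = matrix.matrix
    if m.shape[0] < 2:
        raise ValidationError("need at least 2 trials to form a confidence band")
    n = m.shape[0]
    mean = m.mean(axis=0)
    sd = m.std(axis=0, ddof=1)
    alpha = 1.0 - level / 100.0
    half = stats.t.ppf(1.0 - alpha / 2.0, n - 1) * sd / np.sqrt(n)
    return mean, mean - half, mean + half


def windowed_ci_test(
    matrix: PeriEventMatrix,
    pre_window: tuple[float, float],
    post_window: tuple[float, float],
    levels: Sequence[float] = (95.0, 99.0, 99.9),
) -> CITestResult:
    """Test the event-locked change in window means against zero.

    Per-trial means over ``pre_window`` and ``post_window`` (relative seconds)
    are differenced; a two-sided t interval of the mean difference is formed
    at each level and the change is significant at that level iff the interval
    excludes zero.
    """
    if matrix.n_trials < 2:
        raise ValidationError("windowed_ci_test needs at least 2 trials")
    pre_mask = matrix.window_columns(pre_window)
    post_mask = matrix.window_columns(post_window)
    pre_means = matrix.matrix[:, pre_mask].mean(axis=1)
    post_means = matrix.matrix[:, post_mask].mean(axis=1)
    d = post_means - pre_means
    results: dict[float, CIResult] = {}
    for level in levels:
        lo, hi = _t_interval(d, float(level))
        significant = not (lo <= 0.0 <= hi)
        results[float(level)] = CIResult(float(level), lo, hi, significant)
    return CITestResult(
        levels=results,
        window_means_pre=pre_means,
        window_means_post=post_means,
        diffs=d,
        n=d.size,
    )


def wilcoxon_window_test(pre_means: np.ndarray, post_means: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value for a shift between window means.

    Uses the exact rank-sum null distribution when both groups have n <= 10
    and there are no ties, and the tie-corrected normal approximation
    otherwise (no continuity correction, so identical samples give p = 1).
    """
    x = np.asarray(pre_means, dtype=float)
    y = np.asarray(post_means, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValidationError("each window-mean sample must have size >= 3")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        raise ValidationError(
            "all window means are identical; a rank-sum test is undefined on "
            "ties-only input — check that the windows differ or use the CI test"
        )
    has_ties = np.unique(pooled).size < pooled.size
    if x.size <= 10 and y.size <= 10 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=False
    )
    return float(res.pvalue)


def random_epoch_null(
    trace_values: np.ndarray,
    sample_rate: float,
    n_epochs: int,
    pre_s: float,
    post_s: float,
    exclusion: EventSet | None = None,
    seed: int = 0,
) -> PeriEventMatrix:
    """Peri-event matrix at random epoch centers — a negative control.

    Centers are sampled uniformly (without replacement, on the sample grid)
    among positions whose full window fits in the recording and does not
    overlap any exclusion event's ``[onset, onset + duration)`` span.
    """
    values = np.asarray(trace_values, dtype=float)
    if n_epochs < 1:
        raise ValidationError("n_epochs must be >= 1")
    n = values.size
    lo = int(np.ceil(pre_s * sample_rate))
    hi = n - int(np.ceil(post_s * sample_rate))
    if hi <= lo:
        raise ValidationError("trace too short for the requested windows")
    candidates = np.arange(lo, hi)
    if exclusion is not None and len(exclusion):
        t = candidates / sample_rate
        keep = np.ones(candidates.size, dtype=bool)
        for ev in exclusion:
            dur = ev.duration_s or 0.0
            # window [t-pre, t+post) overlapping [onset, onset+dur]
            keep &= (t + post_s <= ev.onset_s) | (t - pre_s > ev.onset_s + dur)
        candidates = candidates[keep]
    if candidates.size < n_epochs:
        raise ValidationError(
            f"cannot place {n_epochs} epochs: only {candidates.size} admissible centers"
        )
    rng = np.random.default_rng(seed)
    centers = np.sort(rng.choice(candidates, size=n_epochs, replace=False))
    epoch_events = EventSet.from_onsets(centers / sample_rate, label="random_epoch")
    return build_peri_event_matrix(values, sample_rate, epoch_events, pre_s, post_s)
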