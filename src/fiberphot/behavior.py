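"""Behavior-label tracks: numeric encoding, transitions, and ethograms.

Per-frame categorical labels (from a human scorer or an automated classifier)
are treated as data: the category set is declared, not hard-coded. The swim
assay uses {climbing, swimming, hindpaw swimming, immobile} with the
conventional active-to-passive score 4/3/2/1; the photostimulation assay uses
a nine-category set scored in 10-s bins by predominant behavior.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .events import Event, EventSet

__all__ = [
    "SWIM_CATEGORIES",
    "SWIM_SCORE",
    "BehaviorTrack",
    "EthogramBin",
    "PeriodSummary",
    "EthogramSummary",
    "encode_behavior_numeric",
    "mean_behavior_series",
    "detect_transitions",
    "score_ethogram_bins",
    "period_summaries",
    "score_ethogram",
    "TREADING_DIGGING_MERGE",
]

SWIM_CATEGORIES = ("climbing", "swimming", "hindpaw swimming", "immobile")

#: Active-to-passive numeric code for the swim assay.
SWIM_SCORE: dict[str, float] = {
    "climbing": 4.0,
    "swimming": 3.0,
    "hindpaw swimming": 2.0,
    "immobile": 1.0,
}

#: Bedding movement toward or away from the animal is scored as one category.
TREADING_DIGGING_MERGE: dict[str, str] = {
    "treading": "treading/digging",
    "digging": "treading/digging",
}


@dataclass
class BehaviorTrack:
    """Per-frame categorical labels at a declared frame rate."""

    labels: np.ndarray
    frame_rate: float
    categories: tuple[str, ...]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        self.categories = tuple(self.categories)
        if not self.categories:
            raise ValidationError("categories must be a non-empty label set")
        if self.labels.size == 0:
            raise ValidationError("track must contain at least one frame")
        if self.frame_rate <= 0:
            raise ValidationError("frame_rate must be > 0")
        unknown = set(self.labels.tolist()) - set(self.categories)
        if unknown:
            raise ValidationError(
                f"labels outside the declared category set: {sorted(unknown)}"
            )

    @property
    def n_frames(self) -> int:
        return self.labels.size

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate


def encode_behavior_numeric(
    track: BehaviorTrack, mapping: Mapping[str, float] | None = None
) -> np.ndarray:
    """Map each frame's label to a numeric value (default: swim-assay 4..1)."""
    m = dict(mapping) if mapping is not None else dict(SWIM_SCORE)
    missing = [c for c in track.categories if c not in m]
    if missing:
        raise ValidationError(f"mapping does not cover categories: {missing}")
    return np.array([m[lab] for lab in track.labels], dtype=float)


def mean_behavior_series(series: Sequence[np.ndarray]) -> np.ndarray:
    """Per-frame mean of aligned numeric behavior series across animals."""
    if not series:
        raise ValidationError("need at least one series")
    arrays = [np.asarray(s, dtype=float) for s in series]
    lengths = {a.size for a in arrays}
    if len(lengths) != 1:
        raise ValidationError(f"series lengths differ: {sorted(lengths)}")
    return np.mean(np.vstack(arrays), axis=0)


def _run_lengths(labels: np.ndarray) -> list[tuple[int, int, str]]:
    """(start_frame, length, label) for each maximal run."""
    runs = []
    start = 0
    for i in range(1, labels.size + 1):
        if i == labels.size or labels[i] != labels[start]:
            runs.append((start, i - start, labels[start]))
            start = i
    return runs


def detect_transitions(
    track: BehaviorTrack,
    from_states: set[str] | Sequence[str],
    to_state: str,
    min_bout_s: float = 0.5,
) -> EventSet:
    """Onsets where behavior enters ``to_state`` from any of ``from_states``.

    A transition counts only if the new bout lasts at least ``min_bout_s``
    (suppresses classifier flicker). The track starting in ``to_state`` is
    not a transition. Returns an :class:`EventSet` whose durations are the
    bout lengths, ready for peri-event analysis.
    """
    from_set = set(from_states)
    if to_state not in track.categories:
        raise ValidationError(f"to_state {to_state!r} not in category set")
    unknown = from_set - set(track.categories)
    if unknown:
        raise ValidationError(f"from_states not in category set: {sorted(unknown)}")
    if min_bout_s < 0:
        raise ValidationError("min_bout_s must be >= 0")
    events = []
    runs = _run_lengths(track.labels)
    for k, (start, length, label) in enumerate(runs):
        if k == 0 or label != to_state:
            continue
        prev_label = runs[k - 1][2]
        if prev_label not in from_set:
            continue
        if length / track.frame_rate >= min_bout_s - 1e-9:
            events.append(
                Event(
                    onset_s=start / track.frame_rate,
                    duration_s=length / track.frame_rate,
                    label=to_state,
                )
            )
    return EventSet(events)


@dataclass(frozen=True)
class EthogramBin:
    start_s: float
    end_s: float
    category: str
    partial: bool = False


@dataclass(frozen=True)
class PeriodSummary:
    name: str
    start_s: float
    end_s: float
    durations_s: dict[str, float]
    jump_count: int


@dataclass
class EthogramSummary:
    bins: list[EthogramBin] = field(default_factory=list)
    periods: list[PeriodSummary] = field(default_factory=list)


def score_ethogram_bins(
    track: BehaviorTrack,
    bin_s: float = 10.0,
    tie_rule: str = "earliest",
) -> list[EthogramBin]:
    """Predominant behavior per fixed bin (default 10 s).

    Bins tile the track exactly; a trailing bin shorter than ``bin_s`` is
    flagged ``partial``. Ties are broken by ``tie_rule``: ``"earliest"``
    (category appearing first within the bin wins — the default) or
    ``"lexicographic"``.
    """
    if bin_s <= 0:
        raise ValidationError("bin_s must be > 0")
    if tie_rule not in ("earliest", "lexicographic"):
        raise ValidationError(f"unknown tie_rule {tie_rule!r}")
    frames_per_bin = bin_s * track.frame_rate
    n = track.n_frames
    bins: list[EthogramBin] = []
    j = 0
    while True:
        i0 = int(round(j * frames_per_bin))
        if i0 >= n:
            break
        i1 = min(int(round((j + 1) * frames_per_bin)), n)
        chunk = track.labels[i0:i1]
        cats, counts = np.unique(chunk.astype(str), return_counts=True)
        best = counts.max()
        tied = [c for c, k in zip(cats, counts) if k == best]
        if len(tied) == 1 or tie_rule == "lexicographic":
            winner = sorted(tied)[0]
        else:
            first_idx = {c: int(np.argmax(chunk == c)) for c in tied}
            winner = min(tied, key=lambda c: first_idx[c])
        partial = (i1 - i0) < int(round(frames_per_bin))
        bins.append(
            EthogramBin(
                start_s=i0 / track.frame_rate,
                end_s=i1 / track.frame_rate,
                category=winner,
                partial=partial,
            )
        )
        j += 1
    return bins


def _merge_label(label: str, merge_map: Mapping[str, str]) -> str:
    return merge_map.get(label, label)


def period_summaries(
    track: BehaviorTrack,
    jump_events: EventSet,
    periods: Sequence[tuple[str, float, float]],
    merge_map: Mapping[str, str] | None = None,
) -> list[PeriodSummary]:
    """Per-period behavior durations and jump counts.

    ``periods`` is a list of (name, start_s, end_s); periods must not overlap
    and must lie within the track. ``merge_map`` folds categories together at
    scoring time (by default treading and digging are merged into one
    "treading/digging" category).
    """
    merge = dict(merge_map) if merge_map is not None else dict(TREADING_DIGGING_MERGE)
    spans = sorted(periods, key=lambda p: p[1])
    for (_, a0, b0), (_, a1, _b1) in zip(spans, spans[1:]):
        if a1 < b0:
            raise ValidationError("periods overlap")
    out = []
    frame_t = np.arange(track.n_frames) / track.frame_rate
    onsets = jump_events.onsets
    for name, a, b in periods:
        if not (0.0 <= a < b <= track.duration_s + 1e-9):
            raise ValidationError(f"period {name!r} ({a}, {b}) outside the track")
        mask = (frame_t >= a) & (frame_t < b)
        durations: dict[str, float] = {}
        for lab in track.labels[mask]:
            key = _merge_label(str(lab), merge)
            durations[key] = durations.get(key, 0.0) + 1.0 / track.frame_rate
        jumps = int(np.sum((onsets >= a) & (onsets < b))) if onsets.size else 0
        out.append(PeriodSummary(name, a, b, durations, jumps))
    return out


def score_ethogram(
    track: BehaviorTrack,
    jump_events: EventSet | None = None,
    periods: Sequence[tuple[str, float, float]] | None = None,
    bin_s: float = 10.0,
    tie_rule: str = "earliest",
    merge_map: Mapping[str, str] | None = None,
) -> EthogramSummary:
    """Convenience wrapper: binned scoring plus optional period summaries."""
    summary = EthogramSummary(bins=score_ethogram_bins(track, bin_s, tie_rule))
    if periods is not None:
        summary.periods = period_summaries(
            track, jump_events or EventSet(), periods, merge_map
        )
    return summary
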