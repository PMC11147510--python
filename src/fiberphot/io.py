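"""Plain-text readers and writers for the package's data formats.

All formats are simple CSV dialects mirroring multiplexed-acquisition and
event-logger exports, plus a JSON sidecar for synthetic ground truth:

* photometry: ``frame, system_time_s, channel, value``
* events: ``onset_s, duration_s, label`` (duration may be blank)
* behavior labels: ``frame, label``
* trajectory: ``time_s, x_cm, y_cm``
* operant events: ``time_s, port``
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import BehaviorTrack
from .errors import ValidationError
from .events import Event, EventSet
from .preprocess import PhotometryRecording, ProcessedTrace
from .synth import GroundTruth

__all__ = [
    "write_photometry_csv",
    "read_photometry_csv",
    "write_events_csv",
    "read_events_csv",
    "write_behavior_csv",
    "read_behavior_csv",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_operant_csv",
    "read_operant_csv",
    "write_ground_truth_json",
    "read_ground_truth_json",
    "write_processed_csv",
]


def write_photometry_csv(recording: PhotometryRecording, path) -> None:
    recording.frames.to_csv(path, index=False)


def read_photometry_csv(path, combined_rate: float | None = None) -> PhotometryRecording:
    """Read an interleaved frame table; the rate is inferred from timestamps
    (median frame gap) unless given."""
    frames = pd.read_csv(path)
    if combined_rate is None:
        t = frames["system_time_s"].to_numpy(dtype=float)
        if t.size < 2:
            raise ValidationError("cannot infer combined_rate from fewer than 2 frames")
        combined_rate = 1.0 / float(np.median(np.diff(t)))
    return PhotometryRecording(frames, combined_rate=combined_rate)


def write_events_csv(events: EventSet, path) -> None:
    pd.DataFrame(
        {
            "onset_s": [e.onset_s for e in events],
            "duration_s": [e.duration_s for e in events],
            "label": [e.label for e in events],
        }
    ).to_csv(path, index=False)


def read_events_csv(path) -> EventSet:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        dur = row.get("duration_s")
        dur = None if pd.isna(dur) else float(dur)
        out.append(Event(float(row["onset_s"]), dur, str(row.get("label", ""))))
    return EventSet(out)


def write_behavior_csv(track: BehaviorTrack, path) -> None:
    pd.DataFrame(
        {"frame": np.arange(track.n_frames), "label": track.labels}
    ).to_csv(path, index=False)


def read_behavior_csv(
    path, frame_rate: float, categories: tuple[str, ...] | None = None
) -> BehaviorTrack:
    """Read per-frame labels; the category set defaults to the labels seen."""
    df = pd.read_csv(path)
    labels = df["label"].astype(str).to_numpy(dtype=object)
    cats = categories if categories is not None else tuple(sorted(set(labels)))
    return BehaviorTrack(labels, frame_rate, cats)


def write_trajectory_csv(time_s: np.ndarray, xy_cm: np.ndarray, path) -> None:
    pd.DataFrame(
        {"time_s": time_s, "x_cm": xy_cm[:, 0], "y_cm": xy_cm[:, 1]}
    ).to_csv(path, index=False)


def read_trajectory_csv(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return (
        df["time_s"].to_numpy(dtype=float),
        df[["x_cm", "y_cm"]].to_numpy(dtype=float),
    )


def write_operant_csv(events: pd.DataFrame, path) -> None:
    events[["time_s", "port"]].to_csv(path, index=False)


def read_operant_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)[["time_s", "port"]]


def write_ground_truth_json(truth: GroundTruth, path) -> None:
    payload = {
        "transient_onsets": truth.transient_onsets.tolist(),
        "transient_amplitudes": truth.transient_amplitudes.tolist(),
        "step_intervals": [list(s) for s in truth.step_intervals],
        "artifact_times": truth.artifact_times.tolist(),
        "artifact_amplitudes": truth.artifact_amplitudes.tolist(),
        "behavior_schedule": [list(s) for s in truth.behavior_schedule],
        "seed": truth.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth_json(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        transient_onsets=np.array(payload["transient_onsets"], dtype=float),
        transient_amplitudes=np.array(payload["transient_amplitudes"], dtype=float),
        step_intervals=[tuple(s) for s in payload["step_intervals"]],
        artifact_times=np.array(payload["artifact_times"], dtype=float),
        artifact_amplitudes=np.array(payload["artifact_amplitudes"], dtype=float),
        behavior_schedule=tuple(tuple(s) for s in payload["behavior_schedule"]),
        seed=int(payload["seed"]),
    )


def write_processed_csv(trace: ProcessedTrace, path) -> None:
    """Tidy per-sample export of every stage of the signal chain."""
    trace.to_frame().to_csv(path, index=False)
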