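"""Write a synthetic session to the plain-text formats and read it back.

Shows the CSV dialects: interleaved photometry frames, event logs, per-frame
behavior labels, and the ground-truth JSON sidecar.
"""

import tempfile
from pathlib import Path

import fiberphot as fp
from fiberphot import io as fio

spec, events = fp.dunk_protocol(n_trials=3, seed=6)
recording, truth = fp.generate_recording(spec)
track = fp.generate_behavior_track(
    [("swimming", 0.0, spec.duration_s)], 30.0, fp.SWIM_CATEGORIES
)

out = Path(tempfile.mkdtemp())
fio.write_photometry_csv(recording, out / "photometry.csv")
fio.write_events_csv(events, out / "events.csv")
fio.write_behavior_csv(track, out / "behavior.csv")
fio.write_ground_truth_json(truth, out / "truth.json")

back = fio.read_photometry_csv(out / "photometry.csv")
print(f"wrote {len(recording)} frames; read back {len(back)} "
      f"at {back.combined_rate:.0f} frames/s combined")
print(f"events: {len(fio.read_events_csv(out / 'events.csv'))} "
      f"(first onset {events.events[0].onset_s} s)")
print(f"behavior frames: {fio.read_behavior_csv(out / 'behavior.csv', 30.0).n_frames}")

trace = fp.preprocess(back)
fio.write_processed_csv(trace, out / "processed.csv")
print(f"processed stages written to {out / 'processed.csv'}")
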