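"""Generate a synthetic skiing session and inspect its ground truth.

A session is a long six-axis IMU stream: mostly idle time (lift rides,
standing) with a few skiing runs whose turns show up as periodic lateral /
vertical accelerations and body roll.
"""

import skidetect as sk

spec = sk.SessionSpec(
    duration=900.0,
    runs=(
        sk.RunSpec(start=120.0, duration=70.0, turn_frequency=0.5),   # long turns
        sk.RunSpec(start=480.0, duration=55.0, turn_frequency=1.2),   # short turns
    ),
    orientation_events=(),   # the phone stays in one pocket attitude
    sample_rate=100.0,
    seed=3,
)
recording, truth = sk.generate_session(spec)

print(f"{len(recording)} samples at {recording.sample_rate:g} Hz "
      f"({recording.duration:.0f} s)")
for seg in truth:
    print(f"  [{seg.start:6.1f}, {seg.end:6.1f}) s  {seg.label}")

# The label segments partition the session; the two Skiing intervals are the
# runs we asked for, everything else is idle.  write_recording /
# write_segments store both as plain CSV for the CLI or later analysis.
sk.write_recording(recording, "session.csv")
sk.write_segments(truth, "session.labels.csv")
print("wrote session.csv and session.labels.csv")
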