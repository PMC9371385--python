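"""Why orientation tracking comes first: pocket flips move gravity between
body axes, but not in the tracked world frame.

A skier checks the phone mid-session and puts it back differently.  In the
raw body frame the gravity component jumps from one axis to another, which
would give the same activity different features.  After complementary-filter
tracking, gravity stays on world +Y throughout.
"""

import numpy as np

import skidetect as sk
from skidetect.orientation import GRAVITY, quat_from_axis_angle

flip = quat_from_axis_angle([1.0, 0.0, 0.0], np.pi / 2)  # 90 deg pocket flip
spec = sk.SessionSpec(
    duration=120.0,
    orientation_events=((60.0, flip),),
    idle_noise_sd=0.1,
    sample_rate=100.0,
    seed=5,
)
recording, _ = sk.generate_session(spec)

track = sk.track_orientation(recording)
world = sk.to_world(recording, track)

t = recording.timestamps
for label, lo, hi in [("before flip", 20.0, 55.0), ("after flip", 65.0, 115.0)]:
    sel = (t >= lo) & (t < hi)
    body = recording.accel[sel].mean(axis=0)
    wrld = world.accel_world[sel].mean(axis=0)
    print(f"{label:12s} body-frame mean accel  ({body[0]:6.2f}, {body[1]:6.2f}, {body[2]:6.2f})")
    print(f"{'':12s} world-frame mean accel ({wrld[0]:6.2f}, {wrld[1]:6.2f}, {wrld[2]:6.2f})")

print(f"\ngravity stays within {np.abs(world.accel_world[t > 65, 1] - GRAVITY).max():.3f} "
      f"m/s^2 of +Y after the flip (g = {GRAVITY})")
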