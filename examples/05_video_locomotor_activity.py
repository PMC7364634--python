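"""Quantify home-cage locomotor activity by frame differencing.

Motion per frame = number of pixels whose grey level changed by >= 10
relative to the previous frame; per-photoperiod 'relative distance' is the
sum over the period's frames.
"""
import numpy as np

from murisleep import PhotoperiodSchedule, synth
from murisleep.video import motion_trace

schedule = PhotoperiodSchedule()
rng = np.random.default_rng(0)

# an active dark-phase animal: bursts of movement in an otherwise still cage
trace = np.zeros(200)
trace[20:30] = rng.uniform(5, 20, 10)
trace[120:140] = rng.uniform(5, 20, 20)
frames = synth.synthesize_video(trace, frame_shape=(480, 720), seed=1)

tr = motion_trace(frames, schedule, frame_rate=25.0, start_clock_time=18.0)
print(f"Frames: {len(frames)} at 720x480; active frames: {(tr.counts > 0).sum()}")
print(f"Relative distance, dark period:  {tr.period_distance['DARK']:8.0f} px")
print(f"Relative distance, light period: {tr.period_distance['LIGHT']:8.0f} px")
print("\nAll motion was injected after lights-off, so the light-period sum is 0;")
print("the dark-period sum scales with how far the animal moved.")
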