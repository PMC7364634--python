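"""Home-cage locomotor activity from greyscale video frame differencing.

Motion per frame is the count of pixels whose grey level changed by at
least ``grey_delta_min`` (default 10, inclusive) relative to the previous
frame; the per-photoperiod "relative distance" is the sum of those counts
over the period's frames. The per-pixel threshold suppresses video
compression noise; by construction a global luminance step of at least the
threshold flips the whole frame.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .schedule import DARK, LIGHT, PhotoperiodSchedule

__all__ = ["MotionTrace", "frame_motion", "motion_trace"]

GREY_DELTA_MIN = 10


@dataclass
class MotionTrace:
    """Per-frame changed-pixel counts with photoperiod annotation."""

    counts: np.ndarray  # int per frame; first frame = 0 by convention
    frame_rate: float
    photoperiod: np.ndarray  # "LIGHT"/"DARK" per frame
    period_distance: dict[str, float]  # summed counts per photoperiod


def frame_motion(
    prev: np.ndarray, cur: np.ndarray, grey_delta_min: int = GREY_DELTA_MIN
) -> int:
    """Count pixels whose grey level changed by >= ``grey_delta_min``
    (inclusive threshold) between two frames of identical shape."""
    prev = np.asarray(prev)
    cur = np.asarray(cur)
    if prev.shape != cur.shape:
        raise ValueError(f"frame shape mismatch: {prev.shape} vs {cur.shape}")
    diff = np.abs(cur.astype(np.int16) - prev.astype(np.int16))
    return int(np.count_nonzero(diff >= grey_delta_min))


def motion_trace(
    frames: np.ndarray,
    schedule: PhotoperiodSchedule,
    *,
    frame_rate: float = 25.0,
    start_clock_time: float = 6.0,
    grey_delta_min: int = GREY_DELTA_MIN,
) -> MotionTrace:
    """Changed-pixel counts per frame plus per-photoperiod sums.

    The first frame has no predecessor and counts 0 by convention.
    """
    frames = np.asarray(frames)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("need a (n_frames, height, width) stack of >= 2 frames")
    n = frames.shape[0]
    counts = np.zeros(n, dtype=np.int64)
    prev = frames[0].astype(np.int16)
    for t in range(1, n):
        cur = frames[t].astype(np.int16)
        counts[t] = np.count_nonzero(np.abs(cur - prev) >= grey_delta_min)
        prev = cur
    clock = np.mod(start_clock_time + np.arange(n) / frame_rate / 3600.0, 24.0)
    phase = np.asarray(schedule.phase_at(clock), dtype=object)
    period_distance = {
        LIGHT: float(counts[phase == LIGHT].sum()),
        DARK: float(counts[phase == DARK].sum()),
    }
    return MotionTrace(
        counts=counts, frame_rate=frame_rate, photoperiod=phase, period_distance=period_distance
    )
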