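"""Light/dark photoperiod schedule.

Animals are housed under a 12-h light / 12-h dark cycle; most analyses are
split by photoperiod because mice sleep predominantly in the light phase.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

LIGHT = "LIGHT"
DARK = "DARK"


@dataclass(frozen=True)
class PhotoperiodSchedule:
    """A daily light/dark schedule.

    Parameters
    ----------
    lights_on_clock_time:
        Clock time (hours, 0-24) at which the light period starts.
    light_hours, dark_hours:
        Durations of the two phases; they must sum to 24 h.
    """

    lights_on_clock_time: float = 6.0
    light_hours: float = 12.0
    dark_hours: float = 12.0

    def __post_init__(self) -> None:
        if self.light_hours <= 0 or self.dark_hours <= 0:
            raise ValueError("light_hours and dark_hours must both be > 0")
        if abs(self.light_hours + self.dark_hours - 24.0) > 1e-9:
            raise ValueError("light_hours + dark_hours must equal 24")
        if not 0.0 <= self.lights_on_clock_time < 24.0:
            raise ValueError("lights_on_clock_time must lie in [0, 24)")

    def phase_at(self, clock_time: float | np.ndarray) -> np.ndarray | str:
        """Return LIGHT or DARK for a clock time (hours; vectorised)."""
        t = np.asarray(clock_time, dtype=float)
        rel = np.mod(t - self.lights_on_clock_time, 24.0)
        phase = np.where(rel < self.light_hours, LIGHT, DARK)
        if phase.ndim == 0:
            return str(phase)
        return phase

    def is_light(self, clock_time: float | np.ndarray) -> np.ndarray | bool:
        t = np.asarray(clock_time, dtype=float)
        rel = np.mod(t - self.lights_on_clock_time, 24.0)
        out = rel < self.light_hours
        if out.ndim == 0:
            return bool(out)
        return out
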