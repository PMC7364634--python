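"""Hypnogram container: one arousal-state label per scoring epoch."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .schedule import PhotoperiodSchedule
from .states import State


@dataclass
class Hypnogram:
    """Per-epoch arousal-state labels.

    ``labels`` holds :class:`~murisleep.states.State` values (stored as a
    small-int array); ARTEFACT marks epochs removed by quality control.
    """

    labels: np.ndarray
    epoch_seconds: float = 10.0
    start_clock_time: float = 6.0
    schedule: PhotoperiodSchedule = field(default_factory=PhotoperiodSchedule)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.epoch_seconds <= 0:
            raise ValueError("epoch_seconds must be > 0")
        valid = {int(s) for s in State}
        if self.labels.size and not set(np.unique(self.labels)).issubset(valid):
            raise ValueError("labels contain values outside the State enum")

    @property
    def n_epochs(self) -> int:
        return self.labels.size

    def clock_times(self) -> np.ndarray:
        """Start clock time (hours) of each epoch."""
        return np.mod(
            self.start_clock_time + np.arange(self.n_epochs) * self.epoch_seconds / 3600.0,
            24.0,
        )

    def photoperiods(self) -> np.ndarray:
        """LIGHT/DARK annotation per epoch."""
        return np.asarray(self.schedule.phase_at(self.clock_times()), dtype=object)

    def scorable(self) -> np.ndarray:
        """Boolean mask of non-ARTEFACT epochs."""
        return self.labels != int(State.ARTEFACT)
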