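"""In-memory container for one animal-week of EEG/EMG."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .schedule import PhotoperiodSchedule


@dataclass
class Recording:
    """A continuous differential-EEG + nuchal-EMG recording.

    EEG is in microvolts, EMG in arbitrary units; both are sampled at ``fs``
    Hz and have equal length. ``start_clock_time`` anchors the recording to
    the light/dark schedule.
    """

    eeg: np.ndarray
    emg: np.ndarray
    fs: float
    start_clock_time: float = 6.0
    schedule: PhotoperiodSchedule = field(default_factory=PhotoperiodSchedule)
    animal_id: str = "animal-0"
    group: str = "WT"
    age_week: int = 0
    epoch_seconds: float = 10.0

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg, dtype=float)
        self.emg = np.asarray(self.emg, dtype=float)
        if self.eeg.shape != self.emg.shape:
            raise ValueError("eeg and emg must have the same length")
        if self.fs <= 0:
            raise ValueError("fs must be > 0")

    @property
    def n_samples(self) -> int:
        return self.eeg.size

    @property
    def duration_seconds(self) -> float:
        return self.n_samples / self.fs

    @property
    def samples_per_epoch(self) -> int:
        return int(round(self.epoch_seconds * self.fs))

    @property
    def n_epochs(self) -> int:
        return self.n_samples // self.samples_per_epoch
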