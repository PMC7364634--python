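"""Minimal European Data Format (EDF) writer/reader for EEG+EMG recordings.

Writes plain EDF: ASCII headers and 16-bit little-endian samples, one data
record per second, two channels (EEG in uV, EMG in arbitrary units). The
reader inverts the writer and is sufficient for files this package writes;
it is not a general-purpose EDF+ parser.
"""
from __future__ import annotations

import numpy as np

from .recording import Recording
from .schedule import PhotoperiodSchedule

__all__ = ["write_edf", "read_edf"]

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def _num(value: float, width: int) -> bytes:
    for fmt in (f"{{:.{p}g}}" for p in range(10, 0, -1)):
        s = fmt.format(float(value))
        if len(s) <= width:
            return s.ljust(width).encode("ascii")
    raise ValueError(f"cannot format {value} in {width} chars")


def _digitise(x: np.ndarray, phys_min: float, phys_max: float) -> np.ndarray:
    span = phys_max - phys_min
    if span <= 0:
        return np.zeros(x.shape, dtype="<i2")
    scaled = (x - phys_min) / span * (_DIG_MAX - _DIG_MIN) + _DIG_MIN
    return np.clip(np.round(scaled), _DIG_MIN, _DIG_MAX).astype("<i2")


def write_edf(recording: Recording, path) -> None:
    """Write a recording as a 2-channel EDF file (whole seconds only)."""
    fs = recording.fs
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_records = recording.n_samples // spr
    if n_records == 0:
        raise ValueError("recording shorter than one EDF record (1 s)")
    n_keep = n_records * spr
    channels = [
        ("EEG", "uV", recording.eeg[:n_keep]),
        ("EMG", "au", recording.emg[:n_keep]),
    ]
    start_h = int(recording.start_clock_time) % 24
    start_m = int(round((recording.start_clock_time % 1.0) * 60)) % 60
    header = b"".join(
        [
            _field("0", 8),
            _field(recording.animal_id[:80], 80),
            _field(f"group {recording.group} week {recording.age_week}"[:80], 80),
            _field("01.01.20", 8),
            _field(f"{start_h:02d}.{start_m:02d}.00", 8),
            _field(str(256 * (1 + len(channels))), 8),
            _field("", 44),
            _field(str(n_records), 8),
            _field("1", 8),
            _field(str(len(channels)), 4),
        ]
    )
    phys = []
    for _, _, x in channels:
        lo = float(np.min(x)) if x.size else -1.0
        hi = float(np.max(x)) if x.size else 1.0
        if hi <= lo:
            lo, hi = lo - 1.0, hi + 1.0
        phys.append((lo, hi))
    # signal header layout is column-major per EDF: field-by-field blocks
    parts = []
    parts.append(b"".join(_field(name, 16) for name, _, _ in channels))
    parts.append(b"".join(_field("synthetic", 80) for _ in channels))
    parts.append(b"".join(_field(dim, 8) for _, dim, _ in channels))
    parts.append(b"".join(_num(lo, 8) for lo, _ in phys))
    parts.append(b"".join(_num(hi, 8) for _, hi in phys))
    parts.append(b"".join(_num(_DIG_MIN, 8) for _ in channels))
    parts.append(b"".join(_num(_DIG_MAX, 8) for _ in channels))
    parts.append(b"".join(_field("", 80) for _ in channels))
    parts.append(b"".join(_field(str(spr), 8) for _ in channels))
    parts.append(b"".join(_field("", 32) for _ in channels))
    digitised = [
        _digitise(x.reshape(n_records, spr), lo, hi)
        for (_, _, x), (lo, hi) in zip(channels, phys)
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(b"".join(parts))
        for r in range(n_records):
            for d in digitised:
                fh.write(d[r].tobytes())


def read_edf(path) -> Recording:
    """Read an EDF file written by :func:`write_edf` back into a
    :class:`~murisleep.recording.Recording` (EEG + EMG channels)."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        animal_id = head[8:88].decode("ascii").strip()
        rec_id = head[88:168].decode("ascii").strip()
        start_time = head[176:184].decode("ascii")
        n_records = int(head[236:244])
        record_dur = float(head[244:252])
        ns = int(head[252:256])
        sig = fh.read(256 * ns)

        def col(offset_fields: int, width: int, i: int) -> str:
            start = offset_fields + i * width
            return sig[start : start + width].decode("ascii").strip()

        off = 0
        labels = [col(off, 16, i) for i in range(ns)]
        off += 16 * ns + 80 * ns + 8 * ns  # skip transducer & dimension
        phys_min = [float(col(off, 8, i)) for i in range(ns)]
        off += 8 * ns
        phys_max = [float(col(off, 8, i)) for i in range(ns)]
        off += 8 * ns
        dig_min = [float(col(off, 8, i)) for i in range(ns)]
        off += 8 * ns
        dig_max = [float(col(off, 8, i)) for i in range(ns)]
        off += 8 * ns + 80 * ns
        spr = [int(col(off, 8, i)) for i in range(ns)]
        data = {label: [] for label in labels}
        for _ in range(n_records):
            for i, label in enumerate(labels):
                raw = np.frombuffer(fh.read(2 * spr[i]), dtype="<i2").astype(float)
                gain = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
                data[label].append(phys_min[i] + (raw - dig_min[i]) * gain)
    signals = {label: np.concatenate(chunks) for label, chunks in data.items()}
    fs = spr[0] / record_dur
    h, m, _s = (int(v) for v in start_time.split("."))
    group, week = "WT", 0
    toks = rec_id.split()
    if len(toks) >= 4 and toks[0] == "group":
        group, week = toks[1], int(toks[3])
    return Recording(
        eeg=signals.get("EEG", np.empty(0)),
        emg=signals.get("EMG", np.empty(0)),
        fs=fs,
        start_clock_time=h + m / 60.0,
        schedule=PhotoperiodSchedule(),
        animal_id=animal_id,
        group=group,
        age_week=week,
    )
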