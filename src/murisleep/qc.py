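"""Artefact detection and the study's exclusion rules.

Epochs are flagged for clipping (samples pinned near the amplitude rail) or
flat-line (near-zero variance). A recording week is excluded outright when
flagged epochs exceed 5% (strict inequality: exactly 5% is retained). A
separate low-amplitude flag marks weeks whose EEG has collapsed below a
fraction of the animal's baseline power, where staging becomes unreliable;
such weeks are dropped from staging-dependent outcomes but retained for raw
power reporting.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ArtefactReport",
    "detect_clipping",
    "detect_flatline",
    "flag_epochs",
    "apply_week_exclusion",
    "low_amplitude_flag",
]

CLIP = "CLIP"
FLAT = "FLAT"


@dataclass
class ArtefactReport:
    epoch_flags: np.ndarray  # bool per epoch
    reasons: list[str | None]
    artefact_fraction: float
    week_excluded: bool
    low_amplitude_unreliable: bool = False


def detect_clipping(
    epoch_eeg: np.ndarray,
    rail: float,
    *,
    rail_fraction: float = 0.98,
    run_min: int = 5,
    min_fraction: float = 0.01,
) -> bool:
    """True when >= ``min_fraction`` of the epoch's samples sit within
    ``rail_fraction`` of the amplitude rail in runs of >= ``run_min``
    samples. ``rail`` is the week-level observed absolute maximum."""
    x = np.asarray(epoch_eeg, dtype=float)
    if x.size == 0 or rail <= 0:
        return False
    near = np.abs(x) >= rail_fraction * rail
    total = 0
    n = x.size
    i = 0
    while i < n:
        if near[i]:
            j = i
            while j < n and near[j]:
                j += 1
            if j - i >= run_min:
                total += j - i
            i = j
        else:
            i += 1
    return total >= min_fraction * n


def detect_flatline(
    epoch_eeg: np.ndarray,
    fs: float,
    *,
    var_floor: float = 1e-3,
    run_seconds: float = 2.0,
) -> bool:
    """True when any contiguous ``run_seconds`` window of the epoch has
    variance below ``var_floor`` (uV^2)."""
    x = np.asarray(epoch_eeg, dtype=float)
    w = int(round(run_seconds * fs))
    if x.size == 0:
        return False
    if x.size <= w:
        return bool(np.var(x) < var_floor)
    step = max(1, w // 2)
    for start in range(0, x.size - w + 1, step):
        if np.var(x[start : start + w]) < var_floor:
            return True
    # tail window
    return bool(np.var(x[-w:]) < var_floor)


def flag_epochs(
    eeg_epochs: np.ndarray,
    fs: float,
    *,
    rail: float | None = None,
    rail_fraction: float = 0.98,
    clip_run_min: int = 5,
    var_floor: float = 1e-3,
    flat_run_seconds: float = 2.0,
) -> tuple[np.ndarray, list[str | None]]:
    """Flag each epoch of an (n_epochs, samples) array, returning the
    boolean mask and per-epoch reasons. The rail defaults to the observed
    absolute maximum over the whole array (the week-level context)."""
    eeg_epochs = np.asarray(eeg_epochs, dtype=float)
    if rail is None:
        rail = float(np.max(np.abs(eeg_epochs))) if eeg_epochs.size else 0.0
    n = eeg_epochs.shape[0]
    flags = np.zeros(n, dtype=bool)
    reasons: list[str | None] = [None] * n
    for i in range(n):
        if detect_flatline(eeg_epochs[i], fs, var_floor=var_floor, run_seconds=flat_run_seconds):
            flags[i] = True
            reasons[i] = FLAT
        elif detect_clipping(
            eeg_epochs[i], rail, rail_fraction=rail_fraction, run_min=clip_run_min
        ):
            flags[i] = True
            reasons[i] = CLIP
    return flags, reasons


def apply_week_exclusion(
    epoch_flags: np.ndarray,
    reasons: list[str | None] | None = None,
    *,
    threshold: float = 0.05,
) -> ArtefactReport:
    """Apply the week-level exclusion rule: excluded iff the flagged
    fraction strictly exceeds ``threshold`` (default 5%)."""
    flags = np.asarray(epoch_flags, dtype=bool)
    if flags.size == 0:
        raise ValueError("need at least one epoch")
    frac = float(flags.mean())
    if reasons is None:
        reasons = [CLIP if f else None for f in flags]
    return ArtefactReport(
        epoch_flags=flags,
        reasons=list(reasons),
        artefact_fraction=frac,
        week_excluded=frac > threshold,
    )


def low_amplitude_flag(
    weekly_total_power: dict[float, float],
    week: float,
    *,
    floor_fraction: float = 0.2,
) -> bool:
    """True when the week's median total power has fallen below
    ``floor_fraction`` of the animal's first (baseline) week.

    ``weekly_total_power`` maps age_week -> median total power. With no
    baseline week the flag is indeterminate and a ValueError is raised.
    """
    if not weekly_total_power:
        raise ValueError("no weekly total-power series available")
    baseline_week = min(weekly_total_power)
    baseline = weekly_total_power[baseline_week]
    if week not in weekly_total_power:
        raise KeyError(week)
    if floor_fraction <= 0:
        return False
    return weekly_total_power[week] < floor_fraction * baseline
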