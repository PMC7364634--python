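"""Synthetic longitudinal cohort generator.

Emulates the data a longitudinal tauopathy sleep study produces: per-epoch
arousal states from circadian-modulated Markov chains, EEG/EMG signals with
state-typical spectra (1/f background plus band-limited oscillations), epoch
clipping/flat-line artefacts, home-cage video frames, and terminal atrophy
(summed bilateral hippocampus + cortex thickness) coupled to realised
phenotype severity.

Four treatment groups are modelled: wild type (WT), transactivator-only
controls (tTA), tau transgenics (Tg) and doxycycline-suppressed transgenics
(TgDOX). Only the Tg trajectory progresses by default: EEG amplitude
declines multiplicatively per 4-week cycle after onset, dark-phase wake and
home-cage motion increase, and the REM continuation probability shrinks so
REM fragments into mostly 1-epoch episodes.

Every generator is a pure function of (spec, seed).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .hypnogram import Hypnogram
from .recording import Recording
from .schedule import DARK, LIGHT, PhotoperiodSchedule
from .states import SCORABLE_STATES, State

__all__ = [
    "StateSpectrumSpec",
    "TrajectorySpec",
    "CohortSpec",
    "StudyDataset",
    "default_state_specs",
    "default_trajectories",
    "default_transition_matrices",
    "stationary_distribution",
    "simulate_hypnogram",
    "synthesize_signals",
    "inject_artefacts",
    "simulate_study",
    "synthesize_video",
    "frequency_bins",
]

#: Synthesis ceiling (Hz): no power is placed above this frequency.
SYNTH_MAX_HZ = 30.0

_STATE_INDEX = {s: i for i, s in enumerate(SCORABLE_STATES)}


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class StateSpectrumSpec:
    """Spectral signature of one arousal state.

    ``band_power_targets`` maps band name -> power (uV^2) placed uniformly in
    that band; ``background_power`` is the total power of a 1/f background
    over 0.1-30 Hz; ``emg_tone`` is the EMG RMS level (arbitrary units).
    """

    state: State
    band_power_targets: Mapping[str, float]
    emg_tone: float
    amplitude_scale: float = 1.0
    background_power: float = 5.0

    def __post_init__(self) -> None:
        if any(p < 0 for p in self.band_power_targets.values()):
            raise ValueError("band power targets must be >= 0")
        if self.emg_tone < 0 or self.background_power < 0 or self.amplitude_scale < 0:
            raise ValueError("emg_tone, background_power and amplitude_scale must be >= 0")

    def scaled(self, amplitude_scale: float) -> "StateSpectrumSpec":
        return StateSpectrumSpec(
            state=self.state,
            band_power_targets=dict(self.band_power_targets),
            emg_tone=self.emg_tone,
            amplitude_scale=amplitude_scale,
            background_power=self.background_power,
        )


def default_state_specs() -> dict[State, StateSpectrumSpec]:
    """State signatures the stager is built to discriminate.

    NREM is delta-dominated with intermediate muscle tone; REM and
    theta-dominated wake share a 5.1-9 Hz peak and are separated solely by
    EMG (REM atonia); wake is broadband with high EMG.
    """
    specs = {
        State.WAKE: StateSpectrumSpec(
            State.WAKE, {"delta": 40.0, "theta": 40.0, "alpha": 25.0, "beta": 20.0}, emg_tone=3.5
        ),
        State.THETA_WAKE: StateSpectrumSpec(
            State.THETA_WAKE, {"delta": 20.0, "theta": 120.0, "alpha": 12.0, "beta": 6.0}, emg_tone=3.0
        ),
        State.NREM: StateSpectrumSpec(
            State.NREM, {"delta": 200.0, "theta": 40.0, "alpha": 15.0, "beta": 8.0}, emg_tone=1.0
        ),
        State.REM: StateSpectrumSpec(
            State.REM, {"delta": 20.0, "theta": 120.0, "alpha": 12.0, "beta": 6.0}, emg_tone=0.3
        ),
    }
    assert specs[State.REM].emg_tone < specs[State.WAKE].emg_tone  # atonia
    nrem_delta = specs[State.NREM].band_power_targets["delta"]
    assert all(s.band_power_targets["delta"] <= nrem_delta for s in specs.values())
    return specs


@dataclass(frozen=True)
class TrajectorySpec:
    """Progressive phenotype of one treatment group.

    Rates are per 4-week cycle after ``onset_week``:
    ``power_decline_rate`` is the fractional multiplicative amplitude-squared
    (power) decline, ``dark_wake_increase`` adds percentage points to the
    dark-phase wake target, ``rem_fragmentation_rate`` multiplies the REM
    continuation probability, and ``motion_increase`` is the fractional rise
    in dark-phase home-cage motion.
    """

    group: str
    power_decline_rate: float = 0.0
    onset_week: float = 20.0
    dark_wake_increase: float = 0.0
    rem_fragmentation_rate: float = 1.0
    motion_increase: float = 0.0
    #: architecture changes (wake, REM fragmentation, motion) start this many
    #: weeks after the spectral onset: power decline precedes sleep-
    #: architecture change in the modelled phenotype
    architecture_lag_weeks: float = 12.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.power_decline_rate <= 1.0:
            raise ValueError("power_decline_rate must lie in [0, 1]")
        if not 0.0 < self.rem_fragmentation_rate <= 1.0:
            raise ValueError("rem_fragmentation_rate must lie in (0, 1]")
        if self.dark_wake_increase < 0 or self.motion_increase < 0:
            raise ValueError("progression rates must be >= 0")

    def cycles_after_onset(self, week: float) -> float:
        return max(0.0, (week - self.onset_week) / 4.0)

    def architecture_cycles(self, week: float) -> float:
        return max(0.0, (week - self.onset_week - self.architecture_lag_weeks) / 4.0)

    def amplitude_scale(self, week: float) -> float:
        """Amplitude multiplier at ``week``: power declines by
        ``power_decline_rate`` per cycle, so amplitude scales by its root."""
        return float((1.0 - self.power_decline_rate) ** (self.cycles_after_onset(week) / 2.0))


def default_trajectories() -> dict[str, TrajectorySpec]:
    """Study conditions: only Tg progresses; doxycycline suppression and the
    control groups are flat."""
    return {
        "WT": TrajectorySpec("WT"),
        "tTA": TrajectorySpec("tTA"),
        "Tg": TrajectorySpec(
            "Tg",
            power_decline_rate=0.10,
            onset_week=20.0,
            dark_wake_increase=2.0,
            rem_fragmentation_rate=0.80,
            motion_increase=0.15,
            architecture_lag_weeks=12.0,
        ),
        "TgDOX": TrajectorySpec("TgDOX"),
    }


#: Terminal thickness (mm): group mean and SD. Tg atrophies; DOX protects;
#: tTA shows mild thinning relative to WT.
DEFAULT_ATROPHY_LINK: dict[str, tuple[float, float]] = {
    "WT": (3.20, 0.08),
    "tTA": (3.00, 0.08),
    "Tg": (2.50, 0.10),
    "TgDOX": (3.00, 0.08),
}


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic longitudinal cohort."""

    n_per_group: int = 12
    ages: tuple[float, ...] = (20.0, 24.0, 28.0, 32.0, 36.0, 40.0, 44.0)
    seed: int = 0
    epoch_seconds: float = 10.0
    fs: float = 100.0
    groups: tuple[str, ...] = ("WT", "tTA", "Tg", "TgDOX")
    hours_per_record: float = 24.0
    atrophy_link: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ATROPHY_LINK)
    )
    atrophy_coupling: float = 0.05
    amplitude_baseline_sd: float = 0.10
    wake_jitter_points: float = 2.0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if any(b <= a for a, b in zip(self.ages, self.ages[1:])) or not self.ages:
            raise ValueError("ages must be non-empty and strictly increasing")
        if self.fs < 2.0 * SYNTH_MAX_HZ:
            raise ValueError(f"fs must be >= {2 * SYNTH_MAX_HZ} Hz to carry the synthesized spectrum")


# ---------------------------------------------------------------------------
# Markov machinery


def stationary_distribution(matrix: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector
    of eigenvalue 1)."""
    m = np.asarray(matrix, dtype=float)
    w, v = np.linalg.eig(m.T)
    k = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


def _check_stochastic(matrix: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.shape != (4, 4):
        raise ValueError(f"{name} must be 4x4 (WAKE, THETA_WAKE, NREM, REM)")
    if np.any(m < -1e-12) or np.any(np.abs(m.sum(axis=1) - 1.0) > 1e-8):
        raise ValueError(f"{name} must be row-stochastic")
    return np.clip(m, 0.0, None)


def _persistence_matrix(pi: np.ndarray, alpha: float) -> np.ndarray:
    """(1-alpha) I + alpha 1 pi^T: stationary distribution exactly ``pi``
    with state persistence controlled by ``alpha``."""
    pi = np.asarray(pi, dtype=float)
    return (1.0 - alpha) * np.eye(len(pi)) + alpha * np.outer(np.ones(len(pi)), pi)


def default_transition_matrices() -> tuple[np.ndarray, np.ndarray]:
    """Baseline (light, dark) transition matrices.

    Mice sleep mostly in the light phase: the light-phase stationary mix is
    NREM-dominated, the dark phase wake-dominated. Bout structure comes from
    the persistence parameter (10-s epochs; NREM runs of a few minutes).
    """
    light = _persistence_matrix(np.array([0.30, 0.05, 0.55, 0.10]), alpha=0.15)
    dark = _persistence_matrix(np.array([0.55, 0.10, 0.28, 0.07]), alpha=0.20)
    return light, dark


def _blend_toward_wake(matrix: np.ndarray, target_wake: float) -> np.ndarray:
    """Adjust a transition matrix until its stationary wake fraction equals
    ``target_wake``: blend toward all-wake to raise it, toward all-NREM to
    lower it (bisection on the blend weight)."""
    target_wake = float(np.clip(target_wake, 0.05, 0.95))
    base_wake = stationary_distribution(matrix)[_STATE_INDEX[State.WAKE]]
    if abs(target_wake - base_wake) < 1e-12:
        return matrix
    onehot = np.zeros(4)
    raising = target_wake > base_wake
    onehot[_STATE_INDEX[State.WAKE if raising else State.NREM]] = 1.0
    lo, hi = 0.0, 1.0
    for _ in range(60):
        lam = 0.5 * (lo + hi)
        m = (1.0 - lam) * matrix + lam * np.outer(np.ones(4), onehot)
        wake = stationary_distribution(m)[_STATE_INDEX[State.WAKE]]
        if (wake < target_wake) == raising:
            lo = lam
        else:
            hi = lam
    lam = 0.5 * (lo + hi)
    return (1.0 - lam) * matrix + lam * np.outer(np.ones(4), onehot)


def _fragment_rem(matrix: np.ndarray, continuation_multiplier: float) -> np.ndarray:
    """Shrink the REM->REM continuation probability; freed mass wakes the
    animal (REM->WAKE)."""
    m = matrix.copy()
    r = _STATE_INDEX[State.REM]
    w = _STATE_INDEX[State.WAKE]
    old = m[r, r]
    new = old * continuation_multiplier
    m[r, r] = new
    m[r, w] += old - new
    return m


def simulate_hypnogram(
    schedule: PhotoperiodSchedule,
    light_matrix: np.ndarray,
    dark_matrix: np.ndarray,
    duration_hours: float,
    seed: int | np.random.SeedSequence,
    *,
    epoch_seconds: float = 10.0,
    start_clock_time: float | None = None,
    initial_state: State | None = None,
) -> Hypnogram:
    """Simulate per-epoch arousal states from a circadian-modulated Markov
    chain: each epoch uses the transition matrix of its photoperiod phase.
    Same seed, same spec -> identical label sequence.
    """
    light_m = _check_stochastic(light_matrix, "light_matrix")
    dark_m = _check_stochastic(dark_matrix, "dark_matrix")
    if duration_hours <= 0:
        raise ValueError("duration must be positive")
    n_float = duration_hours * 3600.0 / epoch_seconds
    n = int(round(n_float))
    if abs(n_float - n) > 1e-9 or n == 0:
        raise ValueError("duration must be a positive multiple of the epoch length")
    if start_clock_time is None:
        start_clock_time = schedule.lights_on_clock_time
    rng = np.random.default_rng(seed)
    clock = np.mod(start_clock_time + np.arange(n) * epoch_seconds / 3600.0, 24.0)
    is_light = np.asarray(schedule.is_light(clock))
    cum = {True: np.cumsum(light_m, axis=1), False: np.cumsum(dark_m, axis=1)}
    if initial_state is None:
        pi0 = stationary_distribution(light_m if is_light[0] else dark_m)
        state = int(np.searchsorted(np.cumsum(pi0), rng.random(), side="right"))
        state = min(state, 3)
    else:
        state = _STATE_INDEX[State(initial_state)]
    u = rng.random(n)
    labels = np.empty(n, dtype=np.int8)
    for i in range(n):
        row = cum[bool(is_light[i])][state]
        state = int(np.searchsorted(row, u[i], side="right"))
        state = min(state, 3)
        labels[i] = int(SCORABLE_STATES[state])
    return Hypnogram(
        labels=labels,
        epoch_seconds=epoch_seconds,
        start_clock_time=start_clock_time,
        schedule=schedule,
    )


# ---------------------------------------------------------------------------
# signal synthesis


def frequency_bins(n_samples: int, fs: float) -> np.ndarray:
    return np.fft.rfftfreq(n_samples, d=1.0 / fs)


def _epoch_amplitudes(spec: StateSpectrumSpec, n: int, fs: float) -> np.ndarray:
    """Per-rfft-bin oscillation amplitudes realising the spec's band targets
    plus the 1/f background. Band targets are net of the background already
    present in the band (floored at zero), so the in-band total matches the
    target."""
    freqs = frequency_bins(n, fs)
    ceiling = min(SYNTH_MAX_HZ, 0.95 * fs / 2.0)
    power = np.zeros_like(freqs)
    bg_mask = (freqs > 0.1) & (freqs <= ceiling)
    bg_in_band: dict[str, float] = {}
    if spec.background_power > 0 and bg_mask.any():
        shape = 1.0 / freqs[bg_mask]
        bg = spec.background_power * shape / shape.sum()
        power[bg_mask] += bg
        from .bands import DEFAULT_BANDS

        for b in DEFAULT_BANDS:
            sel = (freqs[bg_mask] > b.lo) & (freqs[bg_mask] <= b.hi)
            bg_in_band[b.name] = float(bg[sel].sum())
    from .bands import DEFAULT_BANDS

    band_by_name = {b.name: b for b in DEFAULT_BANDS}
    for name, target in spec.band_power_targets.items():
        if name not in band_by_name:
            raise ValueError(f"unknown band {name!r}")
        b = band_by_name[name]
        sel = (freqs > b.lo) & (freqs <= min(b.hi, ceiling))
        if not sel.any():
            continue
        net = max(0.0, float(target) - bg_in_band.get(name, 0.0))
        power[sel] += net / sel.sum()
    return np.sqrt(2.0 * power) * spec.amplitude_scale


def synthesize_signals(
    hypnogram: Hypnogram,
    specs: Mapping[State, StateSpectrumSpec],
    fs: float,
    seed: int | np.random.SeedSequence,
    *,
    sensor_noise: float = 0.0,
) -> Recording:
    """Synthesize EEG/EMG for every epoch of a hypnogram.

    EEG per epoch is a sum of fixed-amplitude, random-phase oscillations on
    the epoch's Fourier grid, so each epoch's band power equals the state's
    target exactly up to estimator error. EMG is white noise normalised to
    the state's RMS tone. ``sensor_noise`` adds white acquisition noise of
    that RMS (uV) to the EEG, independent of the state amplitude scale --
    the floor that makes scoring collapse when EEG amplitude declines.
    """
    if fs < 100.0:
        raise ValueError("fs must be >= 100 Hz")
    missing = {State(int(l)) for l in np.unique(hypnogram.labels)} - set(specs)
    if missing:
        raise ValueError(f"no StateSpectrumSpec for state(s) {sorted(s.name for s in missing)}")
    rng = np.random.default_rng(seed)
    n = int(round(hypnogram.epoch_seconds * fs))
    n_ep = hypnogram.n_epochs
    amp_by_state = {s: _epoch_amplitudes(spec, n, fs) for s, spec in specs.items()}
    n_bins = len(frequency_bins(n, fs))
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(n_ep, n_bins))
    spectra = np.zeros((n_ep, n_bins), dtype=complex)
    for s, amp in amp_by_state.items():
        sel = hypnogram.labels == int(s)
        if sel.any():
            spectra[sel] = (n / 2.0) * amp * np.exp(1j * phases[sel])
    eeg = np.fft.irfft(spectra, n=n, axis=1)
    if sensor_noise > 0:
        eeg += rng.normal(0.0, sensor_noise, size=eeg.shape)
    emg = rng.standard_normal((n_ep, n))
    for s, spec in specs.items():
        sel = hypnogram.labels == int(s)
        if not sel.any():
            continue
        if spec.emg_tone == 0.0:
            emg[sel] = 0.0
        else:
            block = emg[sel]
            rms = np.sqrt(np.mean(block * block, axis=1, keepdims=True))
            emg[sel] = block * (spec.emg_tone / rms)
    return Recording(
        eeg=eeg.ravel(),
        emg=emg.ravel(),
        fs=fs,
        start_clock_time=hypnogram.start_clock_time,
        schedule=hypnogram.schedule,
        epoch_seconds=hypnogram.epoch_seconds,
    )


def inject_artefacts(
    recording: Recording,
    clip_epochs: Iterable[int] = (),
    flat_epochs: Iterable[int] = (),
    rail: float = 200.0,
) -> tuple[Recording, np.ndarray]:
    """Inject epoch-aligned clipping and flat-line artefacts.

    Clipped epochs are rescaled so well over 10% of samples exceed the rail,
    then saturated at +/-rail; flat epochs are replaced by their mean (zero
    variance). Returns the modified recording and the ground-truth artefact
    mask (one boolean per epoch).
    """
    clip_set = set(int(i) for i in clip_epochs)
    flat_set = set(int(i) for i in flat_epochs)
    if clip_set & flat_set:
        raise ValueError("clip_epochs and flat_epochs must be disjoint")
    n_ep = recording.n_epochs
    bad = (clip_set | flat_set) - set(range(n_ep))
    if bad:
        raise ValueError(f"epoch indices out of range: {sorted(bad)}")
    spe = recording.samples_per_epoch
    eeg = recording.eeg.copy()
    for i in clip_set:
        block = eeg[i * spe : (i + 1) * spe]
        ref = np.quantile(np.abs(block), 0.85)
        if ref <= 0:
            block[:] = rail * np.sign(np.sin(2 * np.pi * np.arange(spe) / spe * 4 + 1e-9))
        else:
            block *= rail / ref
        np.clip(block, -rail, rail, out=block)
        eeg[i * spe : (i + 1) * spe] = block
    for i in flat_set:
        block = eeg[i * spe : (i + 1) * spe]
        eeg[i * spe : (i + 1) * spe] = block.mean()
    mask = np.zeros(n_ep, dtype=bool)
    mask[list(clip_set | flat_set)] = True
    out = Recording(
        eeg=eeg,
        emg=recording.emg.copy(),
        fs=recording.fs,
        start_clock_time=recording.start_clock_time,
        schedule=recording.schedule,
        animal_id=recording.animal_id,
        group=recording.group,
        age_week=recording.age_week,
        epoch_seconds=recording.epoch_seconds,
    )
    return out, mask


# ---------------------------------------------------------------------------
# full study


@dataclass
class StudyDataset:
    """A generated longitudinal study.

    ``truth`` is a long-format table (animal_id, group, age_week,
    photoperiod, outcome, value) of generator-truth metrics; ``scales``
    records the realised per-animal-week amplitude scale; ``atrophy`` holds
    one terminal thickness per animal. Hypnograms are kept per animal-week;
    signals are synthesized on demand via :meth:`recording`.
    """

    cohort: CohortSpec
    trajectories: dict[str, TrajectorySpec]
    schedule: PhotoperiodSchedule
    hypnograms: dict[tuple[str, float], Hypnogram]
    scales: pd.DataFrame
    truth: pd.DataFrame
    atrophy: pd.DataFrame
    state_specs: dict[State, StateSpectrumSpec]

    def amplitude_scale(self, animal_id: str, age_week: float) -> float:
        row = self.scales[
            (self.scales.animal_id == animal_id) & (self.scales.age_week == age_week)
        ]
        if row.empty:
            raise KeyError((animal_id, age_week))
        return float(row.amplitude_scale.iloc[0])

    def recording(
        self, animal_id: str, age_week: float, *, hours: float | None = None
    ) -> Recording:
        """Deterministically synthesize the EEG/EMG of one animal-week
        (optionally truncated to the first ``hours``)."""
        hyp = self.hypnograms[(animal_id, float(age_week))]
        if hours is not None:
            n = int(round(hours * 3600.0 / hyp.epoch_seconds))
            hyp = Hypnogram(
                labels=hyp.labels[:n],
                epoch_seconds=hyp.epoch_seconds,
                start_clock_time=hyp.start_clock_time,
                schedule=hyp.schedule,
            )
        scale = self.amplitude_scale(animal_id, age_week)
        specs = {s: sp.scaled(scale) for s, sp in self.state_specs.items()}
        seed = np.random.SeedSequence(
            entropy=self.cohort.seed,
            spawn_key=(abs(hash(animal_id)) % (2**31), int(age_week)),
        )
        rec = synthesize_signals(hyp, specs, self.cohort.fs, seed)
        rec.animal_id = animal_id
        rec.age_week = int(age_week)
        group = self.scales.loc[self.scales.animal_id == animal_id, "group"].iloc[0]
        rec.group = str(group)
        return rec


def _truth_rows(
    animal_id: str,
    group: str,
    week: float,
    hyp: Hypnogram,
    specs: Mapping[State, StateSpectrumSpec],
    scale: float,
    motion: dict[str, float],
) -> list[dict]:
    """Generator-truth period metrics of one animal-week, long format."""
    light_pm, dark_pm = _metrics.period_metrics(hyp, animal_id=animal_id, group=group, age_week=week)
    rows: list[dict] = []
    for pm in (light_pm, dark_pm):
        frac = {
            State.WAKE: 0.0,
            State.THETA_WAKE: 0.0,
            State.NREM: 0.0,
            State.REM: 0.0,
        }
        phase_mask = hyp.photoperiods() == pm.photoperiod
        labels = hyp.labels[phase_mask]
        scorable = labels != int(State.ARTEFACT)
        n_sc = scorable.sum()
        for s in frac:
            frac[s] = float((labels[scorable] == int(s)).sum()) / max(1, n_sc)
        power2 = scale * scale
        for band in ("delta", "theta"):
            val = power2 * sum(
                frac[s] * (specs[s].band_power_targets.get(band, 0.0)) for s in frac
            )
            rows.append(_row(animal_id, group, week, pm.photoperiod, f"{band}_power", val))
        total = power2 * sum(
            frac[s]
            * (sum(specs[s].band_power_targets.values()) + specs[s].background_power)
            for s in frac
        )
        rows.append(_row(animal_id, group, week, pm.photoperiod, "total_power", total))
        for name, val in (
            ("pct_wake", pm.pct_wake),
            ("pct_nrem", pm.pct_nrem),
            ("pct_rem", pm.pct_rem),
            ("sleep_bout_count", pm.sleep_bout_count),
            ("sleep_bout_mean_len_s", pm.sleep_bout_mean_len_s),
            ("rem_bout_count", pm.rem_bout_count),
            ("rem_bout_mean_len_s", pm.rem_bout_mean_len_s),
        ):
            rows.append(_row(animal_id, group, week, pm.photoperiod, name, val))
        rows.append(_row(animal_id, group, week, pm.photoperiod, "motion", motion[pm.photoperiod]))
    return rows


def _row(animal_id, group, week, phase, outcome, value) -> dict:
    return {
        "animal_id": animal_id,
        "group": group,
        "age_week": week,
        "photoperiod": phase,
        "outcome": outcome,
        "value": float(value),
    }


def simulate_study(
    cohort: CohortSpec,
    trajectories: Mapping[str, TrajectorySpec] | None = None,
) -> StudyDataset:
    """Generate a full longitudinal cohort.

    Per animal-week, a hypnogram is simulated from phase-specific transition
    matrices modulated by the group trajectory; the realised amplitude scale,
    truth metrics and dark/light motion are tabulated. Terminal atrophy is
    drawn per animal as group mean + coupling x (within-group standardised
    final dark-phase NREM%) + noise, so actual- and residual-correlation
    behaviour can both be dialled in. Same cohort spec -> identical dataset.
    """
    if trajectories is None:
        trajectories = default_trajectories()
    missing = set(cohort.groups) - set(trajectories)
    if missing:
        raise ValueError(f"missing TrajectorySpec for group(s) {sorted(missing)}")
    schedule = PhotoperiodSchedule()
    light_base, dark_base = default_transition_matrices()
    base_dark_wake = stationary_distribution(dark_base)[_STATE_INDEX[State.WAKE]]
    specs = default_state_specs()
    root = np.random.SeedSequence(cohort.seed)
    hypnograms: dict[tuple[str, float], Hypnogram] = {}
    scale_rows: list[dict] = []
    truth_rows: list[dict] = []
    final_nrem: dict[str, float] = {}
    animal_groups: dict[str, str] = {}
    base_dark_motion, base_light_motion = 100.0, 30.0
    for gi, group in enumerate(cohort.groups):
        traj = trajectories[group]
        for j in range(cohort.n_per_group):
            animal_id = f"{group}-{j:02d}"
            animal_groups[animal_id] = group
            a_ss = np.random.SeedSequence(entropy=cohort.seed, spawn_key=(gi, j))
            a_rng = np.random.default_rng(a_ss)
            amp_baseline = float(np.exp(a_rng.normal(0.0, cohort.amplitude_baseline_sd)))
            wake_jitter = float(a_rng.normal(0.0, cohort.wake_jitter_points))
            motion_jitter = float(np.exp(a_rng.normal(0.0, 0.10)))
            for wi, week in enumerate(cohort.ages):
                arch_cycles = traj.architecture_cycles(week)
                scale = amp_baseline * traj.amplitude_scale(week)
                target_wake = (
                    base_dark_wake
                    + (traj.dark_wake_increase * arch_cycles + wake_jitter) / 100.0
                )
                # fragment first, then pin the stationary wake fraction, so
                # dark_wake_increase is the realised points-per-cycle change
                frag = traj.rem_fragmentation_rate**arch_cycles
                dark_m = _blend_toward_wake(_fragment_rem(dark_base, frag), target_wake)
                light_m = _fragment_rem(light_base, frag)
                hyp = simulate_hypnogram(
                    schedule,
                    light_m,
                    dark_m,
                    cohort.hours_per_record,
                    np.random.SeedSequence(entropy=cohort.seed, spawn_key=(gi, j, wi)),
                    epoch_seconds=cohort.epoch_seconds,
                )
                hypnograms[(animal_id, float(week))] = hyp
                scale_rows.append(
                    {
                        "animal_id": animal_id,
                        "group": group,
                        "age_week": float(week),
                        "amplitude_scale": scale,
                    }
                )
                motion = {
                    DARK: base_dark_motion
                    * (1.0 + traj.motion_increase * arch_cycles)
                    * motion_jitter,
                    LIGHT: base_light_motion * motion_jitter,
                }
                truth_rows.extend(_truth_rows(animal_id, group, float(week), hyp, specs, scale, motion))
            last = hypnograms[(animal_id, float(cohort.ages[-1]))]
            phase = last.photoperiods()
            dark_labels = last.labels[phase == DARK]
            final_nrem[animal_id] = float(
                (dark_labels == int(State.NREM)).mean() * 100.0
            )
    truth = pd.DataFrame(truth_rows)
    scales = pd.DataFrame(scale_rows)
    atrophy_rows: list[dict] = []
    for gi, group in enumerate(cohort.groups):
        ids = [a for a, g in animal_groups.items() if g == group]
        vals = np.array([final_nrem[a] for a in ids])
        sd = vals.std(ddof=0)
        z = (vals - vals.mean()) / sd if sd > 0 else np.zeros_like(vals)
        mean_mm, sd_mm = cohort.atrophy_link[group]
        g_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=cohort.seed, spawn_key=(1000 + gi,))
        )
        noise = g_rng.normal(0.0, sd_mm, size=len(ids))
        for a, zi, ni in zip(ids, z, noise):
            atrophy_rows.append(
                {
                    "animal_id": a,
                    "group": group,
                    "thickness_mm": mean_mm + cohort.atrophy_coupling * zi + ni,
                }
            )
    return StudyDataset(
        cohort=cohort,
        trajectories=dict(trajectories),
        schedule=schedule,
        hypnograms=hypnograms,
        scales=scales,
        truth=truth,
        atrophy=pd.DataFrame(atrophy_rows),
        state_specs=specs,
    )


# ---------------------------------------------------------------------------
# video


def synthesize_video(
    motion_trace: np.ndarray,
    frame_shape: tuple[int, int] = (480, 720),
    seed: int | np.random.SeedSequence = 0,
    *,
    block_size: int = 20,
    background_level: int = 100,
    block_level: int = 140,
) -> np.ndarray:
    """Greyscale frame sequence encoding a motion trace.

    A square block displaces along a horizontal track by ``round(intensity)``
    pixels per frame, so the number of changed pixels between consecutive
    frames is 2 x block_height x min(displacement, block_size) -- monotone
    non-decreasing in the frame's intensity. Zero intensity leaves the frame
    identical to its predecessor. Same seed -> identical frames.
    """
    trace = np.asarray(motion_trace, dtype=float)
    if np.any(trace < 0):
        raise ValueError("motion intensities must be >= 0")
    h, w = frame_shape
    if block_size >= min(h, w):
        raise ValueError("block_size must fit inside the frame")
    rng = np.random.default_rng(seed)
    track = w - block_size
    x = int(rng.integers(0, max(1, track // 4)))
    y = int(rng.integers(0, h - block_size))
    frames = np.full((len(trace), h, w), background_level, dtype=np.uint8)
    for t, intensity in enumerate(trace):
        if t > 0:
            x = (x + int(round(intensity))) % track
        frames[t, y : y + block_size, x : x + block_size] = block_level
    return frames
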