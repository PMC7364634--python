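"""Sleep architecture, continuity and circadian outcomes from hypnograms.

Definitions follow the study's scoring conventions: sleep bouts are maximal
runs of sleep (NREM + REM) epochs qualifying via at least 3 consecutive NREM
epochs or at least 2 consecutive REM epochs; REM bouts are maximal REM runs
of at least 2 epochs. With 10-s epochs the minimal reported sleep bout is
30 s and the minimal REM bout 20 s. Theta-dominated wake is reported merged
into wake; percentages are computed over scorable (non-artefact) epochs.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .hypnogram import Hypnogram
from .schedule import DARK, LIGHT
from .states import SLEEP_STATES, State, WAKE_LIKE

__all__ = [
    "Bout",
    "PeriodMetrics",
    "detect_bouts",
    "time_in_state",
    "rem_episode_distribution",
    "circadian_amplitude",
    "weekly_aggregate",
    "period_metrics",
]


@dataclass(frozen=True)
class Bout:
    kind: str  # "SLEEP" or "REM"
    start_epoch: int
    n_epochs: int

    def duration_seconds(self, epoch_seconds: float = 10.0) -> float:
        return self.n_epochs * epoch_seconds


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, length)."""
    out = []
    n = len(mask)
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            out.append((i, j - i))
            i = j
        else:
            i += 1
    return out


def _max_consecutive(labels: np.ndarray, state: State) -> int:
    best = cur = 0
    for v in labels:
        if v == int(state):
            cur += 1
            best = max(best, cur)
        else:
            cur = 0
    return best


def detect_bouts(
    hypnogram: Hypnogram,
    *,
    min_sleep_epochs: int = 3,
    nrem_only: bool = False,
) -> list[Bout]:
    """Detect SLEEP and REM bouts.

    A maximal run of sleep epochs (NREM or REM; artefact epochs break runs)
    is a SLEEP bout when it spans at least ``min_sleep_epochs`` epochs and
    contains >=3 consecutive NREM epochs or >=2 consecutive REM epochs.
    ``min_sleep_epochs=2`` admits an isolated REM pair as a 20-s sleep bout;
    ``nrem_only=True`` restricts sleep bouts to maximal NREM runs of >=3.
    REM bouts are maximal REM runs of >=2 epochs regardless of mode.
    """
    labels = hypnogram.labels
    bouts: list[Bout] = []
    if nrem_only:
        sleep_mask = labels == int(State.NREM)
        for start, length in _runs(sleep_mask):
            if length >= 3:
                bouts.append(Bout("SLEEP", start, length))
    else:
        sleep_mask = np.isin(labels, [int(s) for s in SLEEP_STATES])
        for start, length in _runs(sleep_mask):
            seg = labels[start : start + length]
            if length >= min_sleep_epochs and (
                _max_consecutive(seg, State.NREM) >= 3 or _max_consecutive(seg, State.REM) >= 2
            ):
                bouts.append(Bout("SLEEP", start, length))
    rem_mask = labels == int(State.REM)
    for start, length in _runs(rem_mask):
        if length >= 2:
            bouts.append(Bout("REM", start, length))
    return bouts


def time_in_state(hypnogram: Hypnogram) -> dict[str, dict[str, float]]:
    """State percentages and minutes per photoperiod.

    Percentages use scorable epochs as the denominator; theta-dominated wake
    counts as wake. An all-artefact period yields NaN percentages and
    ``valid=False``.
    """
    phases = hypnogram.photoperiods()
    labels = hypnogram.labels
    out: dict[str, dict[str, float]] = {}
    minutes_per_epoch = hypnogram.epoch_seconds / 60.0
    for phase in (LIGHT, DARK):
        sel = phases == phase
        lab = labels[sel]
        scorable = lab != int(State.ARTEFACT)
        n_sc = int(scorable.sum())
        lab_sc = lab[scorable]
        n_wake = int(np.isin(lab_sc, [int(s) for s in WAKE_LIKE]).sum())
        n_nrem = int((lab_sc == int(State.NREM)).sum())
        n_rem = int((lab_sc == int(State.REM)).sum())
        if n_sc == 0:
            out[phase] = {
                "pct_wake": np.nan,
                "pct_nrem": np.nan,
                "pct_rem": np.nan,
                "minutes_wake": 0.0,
                "minutes_nrem": 0.0,
                "minutes_rem": 0.0,
                "n_scorable": 0,
                "valid": False,
            }
            continue
        out[phase] = {
            "pct_wake": 100.0 * n_wake / n_sc,
            "pct_nrem": 100.0 * n_nrem / n_sc,
            "pct_rem": 100.0 * n_rem / n_sc,
            "minutes_wake": n_wake * minutes_per_epoch,
            "minutes_nrem": n_nrem * minutes_per_epoch,
            "minutes_rem": n_rem * minutes_per_epoch,
            "n_scorable": n_sc,
            "valid": True,
        }
    return out


def rem_episode_distribution(hypnogram: Hypnogram) -> dict[int, int]:
    """Histogram of maximal REM run lengths, including 1-epoch episodes
    (sub-bout REM fragments)."""
    rem_mask = hypnogram.labels == int(State.REM)
    hist: dict[int, int] = {}
    for _, length in _runs(rem_mask):
        hist[length] = hist.get(length, 0) + 1
    return hist


@dataclass
class PeriodMetrics:
    """Per animal x week x photoperiod summary."""

    animal_id: str
    group: str
    age_week: float
    photoperiod: str
    pct_wake: float = np.nan
    pct_nrem: float = np.nan
    pct_rem: float = np.nan
    sleep_bout_count: float = 0.0
    sleep_bout_mean_len_s: float = np.nan
    rem_bout_count: float = 0.0
    rem_bout_mean_len_s: float = np.nan
    band_power_means: dict[str, float] = field(default_factory=dict)
    n_scorable_epochs: int = 0
    excluded: bool = False


def period_metrics(
    hypnogram: Hypnogram,
    *,
    animal_id: str = "",
    group: str = "",
    age_week: float = 0.0,
    features: Sequence | None = None,
    **bout_kwargs,
) -> tuple[PeriodMetrics, PeriodMetrics]:
    """Summarise one recording into (LIGHT, DARK) :class:`PeriodMetrics`.

    Bouts are assigned to the photoperiod of their start epoch. When
    per-epoch ``features`` (from :func:`murisleep.sigproc.extract_features`)
    are given, per-band power means are included, plus NREM-restricted delta
    power under the key ``"delta_nrem"``.
    """
    tis = time_in_state(hypnogram)
    phases = hypnogram.photoperiods()
    bouts = detect_bouts(hypnogram, **bout_kwargs)
    out = []
    for phase in (LIGHT, DARK):
        pm = PeriodMetrics(
            animal_id=animal_id,
            group=group,
            age_week=age_week,
            photoperiod=phase,
            pct_wake=tis[phase]["pct_wake"],
            pct_nrem=tis[phase]["pct_nrem"],
            pct_rem=tis[phase]["pct_rem"],
            n_scorable_epochs=int(tis[phase]["n_scorable"]),
            excluded=not tis[phase]["valid"],
        )
        for kind in ("SLEEP", "REM"):
            ours = [
                b for b in bouts if b.kind == kind and phases[b.start_epoch] == phase
            ]
            count = len(ours)
            mean_len = (
                float(np.mean([b.n_epochs for b in ours])) * hypnogram.epoch_seconds
                if ours
                else np.nan
            )
            if kind == "SLEEP":
                pm.sleep_bout_count = count
                pm.sleep_bout_mean_len_s = mean_len
            else:
                pm.rem_bout_count = count
                pm.rem_bout_mean_len_s = mean_len
        if features is not None:
            sel = [
                f
                for i, f in enumerate(features)
                if phases[min(i, len(phases) - 1)] == phase and not f.artefact
            ]
            if sel:
                band_names = sel[0].band_power.keys()
                pm.band_power_means = {
                    name: float(np.mean([f.band_power[name] for f in sel])) for name in band_names
                }
                pm.band_power_means["total"] = float(np.mean([f.total_power for f in sel]))
                nrem_sel = [
                    f
                    for i, f in enumerate(features)
                    if phases[min(i, len(phases) - 1)] == phase
                    and not f.artefact
                    and hypnogram.labels[i] == int(State.NREM)
                ]
                if nrem_sel:
                    pm.band_power_means["delta_nrem"] = float(
                        np.mean([f.band_power["delta"] for f in nrem_sel])
                    )
        out.append(pm)
    return out[0], out[1]


def circadian_amplitude(light_metrics: PeriodMetrics, dark_metrics: PeriodMetrics) -> float:
    """Light-minus-dark NREM percentage (signed, percentage points)."""
    if light_metrics.excluded or dark_metrics.excluded:
        raise ValueError("cannot compute circadian amplitude from excluded periods")
    if (
        light_metrics.animal_id != dark_metrics.animal_id
        or light_metrics.age_week != dark_metrics.age_week
    ):
        raise ValueError("light and dark metrics must come from the same animal-week")
    return float(light_metrics.pct_nrem - dark_metrics.pct_nrem)


_MEAN_FIELDS = (
    "pct_wake",
    "pct_nrem",
    "pct_rem",
    "sleep_bout_count",
    "sleep_bout_mean_len_s",
    "rem_bout_count",
    "rem_bout_mean_len_s",
)


def weekly_aggregate(daily: Iterable[PeriodMetrics]) -> PeriodMetrics:
    """Unweighted mean of per-day metrics over one 4-week-cycle recording
    week; days already excluded are dropped, and a week with no retained day
    is returned marked excluded."""
    daily = list(daily)
    if not daily:
        raise ValueError("no daily metrics supplied")
    keys = {(d.animal_id, d.age_week, d.photoperiod) for d in daily}
    if len(keys) != 1:
        raise ValueError("daily metrics must share animal, week and photoperiod")
    retained = [d for d in daily if not d.excluded]
    template = daily[0]
    agg = PeriodMetrics(
        animal_id=template.animal_id,
        group=template.group,
        age_week=template.age_week,
        photoperiod=template.photoperiod,
    )
    if not retained:
        agg.excluded = True
        return agg
    for name in _MEAN_FIELDS:
        vals = [getattr(d, name) for d in retained]
        vals = [v for v in vals if not (isinstance(v, float) and np.isnan(v))]
        setattr(agg, name, float(np.mean(vals)) if vals else np.nan)
    band_names = set().union(*(d.band_power_means.keys() for d in retained))
    for name in band_names:
        vals = [d.band_power_means[name] for d in retained if name in d.band_power_means]
        agg.band_power_means[name] = float(np.mean(vals))
    agg.n_scorable_epochs = int(np.sum([d.n_scorable_epochs for d in retained]))
    return agg


def metrics_table(period_metrics_list: Iterable[PeriodMetrics]) -> pd.DataFrame:
    """Long-format table (animal_id, group, age_week, photoperiod, outcome,
    value) for the longitudinal statistics module."""
    rows = []
    for pm in period_metrics_list:
        if pm.excluded:
            continue
        base = {
            "animal_id": pm.animal_id,
            "group": pm.group,
            "age_week": pm.age_week,
            "photoperiod": pm.photoperiod,
        }
        for name in _MEAN_FIELDS:
            rows.append({**base, "outcome": name, "value": getattr(pm, name)})
        for name, val in pm.band_power_means.items():
            rows.append({**base, "outcome": f"power_{name}", "value": val})
    return pd.DataFrame(rows)
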