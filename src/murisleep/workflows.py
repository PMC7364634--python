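"""End-to-end analysis workflows over simulated or recorded cohorts.

These compose the module pipeline the way the study design prescribes:
signals -> epoch features -> (staging) -> period metrics -> long-format
study table -> repeated-measures contrasts.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .bands import DELTA
from .sigproc import band_power
from .states import State
from .synth import StudyDataset

__all__ = ["measure_study_outcomes", "first_significant_age"]


def measure_study_outcomes(
    dataset: StudyDataset,
    *,
    signal_hours: float = 1.0,
    state_outcomes: tuple[str, ...] = ("pct_wake", "pct_nrem", "pct_rem",
                                       "rem_bout_count", "sleep_bout_count"),
) -> pd.DataFrame:
    """Measure per-animal-week outcomes from a simulated study.

    Spectral outcome: NREM-restricted delta power ("delta_power_nrem"),
    measured by Welch band power over the first ``signal_hours`` of
    synthesized signal (epochs selected by the hypnogram's NREM labels).
    Architecture outcomes come from the full hypnograms via
    :func:`murisleep.metrics.period_metrics`, per photoperiod.

    Returns a long table (animal_id, group, age_week, photoperiod, outcome,
    value) ready for :func:`murisleep.stats.fit_repeated_measures`.
    """
    rows: list[dict] = []
    groups = dataset.scales.set_index("animal_id").group.to_dict()
    for (animal, week), hyp in dataset.hypnograms.items():
        group = groups[animal]
        light_pm, dark_pm = _metrics.period_metrics(
            hyp, animal_id=animal, group=group, age_week=week
        )
        for pm in (light_pm, dark_pm):
            for name in state_outcomes:
                rows.append(
                    {
                        "animal_id": animal,
                        "group": group,
                        "age_week": week,
                        "photoperiod": pm.photoperiod,
                        "outcome": name,
                        "value": float(getattr(pm, name)),
                    }
                )
        rec = dataset.recording(animal, week, hours=signal_hours)
        spe = rec.samples_per_epoch
        powers = [
            band_power(rec.eeg[i * spe : (i + 1) * spe], rec.fs, DELTA)
            for i in range(rec.n_epochs)
            if hyp.labels[i] == int(State.NREM)
        ]
        if powers:
            # spectral power is photoperiod-independent in the generator;
            # report it under both periods for a uniform table
            for phase in ("LIGHT", "DARK"):
                rows.append(
                    {
                        "animal_id": animal,
                        "group": group,
                        "age_week": week,
                        "photoperiod": phase,
                        "outcome": "delta_power_nrem",
                        "value": float(np.mean(powers)),
                    }
                )
    return pd.DataFrame(rows)


def first_significant_age(contrasts, group_a: str, group_b: str) -> float | None:
    """Earliest age at which the (group_a, group_b) contrast is significant,
    or None."""
    ages = sorted(
        c.age_week
        for c in contrasts
        if {c.group_a, c.group_b} == {group_a, group_b} and c.significant
    )
    return ages[0] if ages else None
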