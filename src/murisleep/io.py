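"""Plain-text I/O: hypnogram / feature / metrics CSV and YAML study configs."""
from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .bands import DEFAULT_BANDS
from .hypnogram import Hypnogram
from .schedule import PhotoperiodSchedule
from .sigproc import EpochFeatures
from .states import State
from .synth import CohortSpec, TrajectorySpec

__all__ = [
    "hypnogram_to_frame",
    "write_hypnogram_csv",
    "read_hypnogram_csv",
    "features_to_frame",
    "write_features_csv",
    "cohort_from_yaml",
    "trajectories_from_yaml",
]


def hypnogram_to_frame(hyp: Hypnogram) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "epoch_index": np.arange(hyp.n_epochs),
            "clock_time": hyp.clock_times(),
            "photoperiod": hyp.photoperiods(),
            "state": [State(int(v)).name for v in hyp.labels],
        }
    )


def write_hypnogram_csv(hyp: Hypnogram, path) -> None:
    hypnogram_to_frame(hyp).to_csv(path, index=False)


def read_hypnogram_csv(
    path, *, epoch_seconds: float = 10.0, schedule: PhotoperiodSchedule | None = None
) -> Hypnogram:
    df = pd.read_csv(path)
    labels = np.array([int(State[s]) for s in df["state"]], dtype=np.int8)
    start = float(df["clock_time"].iloc[0]) if len(df) else 0.0
    return Hypnogram(
        labels=labels,
        epoch_seconds=epoch_seconds,
        start_clock_time=start,
        schedule=schedule or PhotoperiodSchedule(),
    )


def features_to_frame(features: Sequence[EpochFeatures]) -> pd.DataFrame:
    rows = []
    for f in features:
        row = {
            "epoch_index": f.epoch_index,
            "clock_time": f.clock_time,
            "photoperiod": f.photoperiod,
            "total_power": f.total_power,
            "emg_rms": f.emg_rms,
            "artefact": f.artefact,
        }
        for b in DEFAULT_BANDS:
            row[f"power_{b.name}"] = f.band_power[b.name]
            row[f"hw_count_{b.name}"] = f.halfwave_incidence[b.name]
            row[f"hw_amp_{b.name}"] = f.halfwave_amplitude[b.name]
        rows.append(row)
    return pd.DataFrame(rows)


def write_features_csv(features: Sequence[EpochFeatures], path) -> None:
    features_to_frame(features).to_csv(path, index=False)


def cohort_from_yaml(path) -> CohortSpec:
    """Load a :class:`~murisleep.synth.CohortSpec` from a YAML mapping."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "ages" in raw:
        raw["ages"] = tuple(float(a) for a in raw["ages"])
    if "groups" in raw:
        raw["groups"] = tuple(raw["groups"])
    if "atrophy_link" in raw:
        raw["atrophy_link"] = {g: tuple(v) for g, v in raw["atrophy_link"].items()}
    return CohortSpec(**raw)


def trajectories_from_yaml(path) -> dict[str, TrajectorySpec]:
    """Load group trajectories from a YAML mapping group -> parameters."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return {g: TrajectorySpec(group=g, **(params or {})) for g, params in raw.items()}
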