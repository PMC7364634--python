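"""Epoch classification into wake, theta-dominated wake, NREM and REM.

Each animal gets its own state templates (centroids over standardised epoch
features) and EMG thresholds, refit from each recording week so the
classifier tracks amplitude drift. Classification is by ranked membership:
for every feature the candidate states are ranked by closeness of the
epoch's value to each centroid's value, and the state with the smallest mean
rank wins, after EMG overrides (REM requires atonia; an atonic,
theta-dominant 'wake' epoch is re-labelled REM).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.cluster import KMeans

from .hypnogram import Hypnogram
from .recording import Recording
from .sigproc import EpochFeatures, FEATURE_NAMES, extract_features, feature_matrix
from .states import SCORABLE_STATES, State, TIEBREAK_ORDER

__all__ = ["StateTemplateSet", "fit_templates", "rank_membership_classify", "score_recording"]

_EMG_IDX = FEATURE_NAMES.index("emg_rms")
_THETA_IDX = FEATURE_NAMES.index("power_theta")
_DELTA_IDX = FEATURE_NAMES.index("power_delta")

#: Extra weight on the EMG dimension during clustering only. REM and
#: theta-dominated wake share an EEG signature and are separated by muscle
#: tone alone, so EMG must carry comparable weight to the EEG block.
_EMG_CLUSTER_WEIGHT = 4.0


@dataclass
class StateTemplateSet:
    """Per-animal state centroids (standardised feature space) and EMG
    criteria."""

    animal_id: str
    centroids: dict[State, np.ndarray]
    emg_wake_threshold: float
    emg_atonia_threshold: float
    feature_center: np.ndarray
    feature_scale: np.ndarray

    def __post_init__(self) -> None:
        if self.emg_atonia_threshold >= self.emg_wake_threshold:
            raise ValueError("emg_atonia_threshold must be below emg_wake_threshold")
        states = list(self.centroids)
        for i, a in enumerate(states):
            for b in states[i + 1 :]:
                if np.allclose(self.centroids[a], self.centroids[b]):
                    raise ValueError(f"degenerate templates: {a.name} and {b.name} coincide")

    def standardise(self, x: np.ndarray) -> np.ndarray:
        return (x - self.feature_center) / self.feature_scale


def _standardisation(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    center = x.mean(axis=0)
    scale = x.std(axis=0)
    scale[scale == 0] = 1.0
    return center, scale


def _emg_thresholds(emg_by_state: dict[State, np.ndarray]) -> tuple[float, float]:
    """Midpoints between state-wise EMG RMS medians: atonia threshold
    between REM and NREM, wake threshold between NREM and the lower of the
    two wake states."""
    med = {s: float(np.median(v)) for s, v in emg_by_state.items()}
    atonia = 0.5 * (med[State.REM] + med[State.NREM])
    wake = 0.5 * (med[State.NREM] + min(med[State.WAKE], med[State.THETA_WAKE]))
    return wake, atonia


def fit_templates(
    features: Sequence[EpochFeatures],
    *,
    seed_labels: Sequence[State | int] | None = None,
    animal_id: str = "",
    random_state: int = 0,
) -> StateTemplateSet:
    """Fit per-animal state templates.

    Labelled mode (``seed_labels`` gives a state, or None, per epoch):
    centroids are per-state means of standardised seed features; at least 5
    seeds per state are required. Unsupervised mode: k-means (k=4, 20
    restarts, fixed seed) on the standardised features followed by semantic
    assignment -- highest delta power -> NREM, then highest EMG -> WAKE, and
    of the remaining two theta clusters the atonic one -> REM, the other ->
    THETA_WAKE. EMG thresholds sit at midpoints between state-wise medians.
    """
    usable = [f for f in features if not f.artefact]
    if len(usable) < 50:
        raise ValueError("need at least 50 non-artefact epochs to fit templates")
    x = feature_matrix(usable)
    center, scale = _standardisation(x)
    z = (x - center) / scale
    emg_raw = x[:, _EMG_IDX]

    if seed_labels is not None:
        labels_full = list(seed_labels)
        if len(labels_full) != len(features):
            raise ValueError("seed_labels must align with features")
        lab = np.array(
            [-1 if l is None else int(l) for l, f in zip(labels_full, features) if not f.artefact]
        )
        centroids: dict[State, np.ndarray] = {}
        emg_by_state: dict[State, np.ndarray] = {}
        for s in SCORABLE_STATES:
            sel = lab == int(s)
            if sel.sum() < 5:
                raise ValueError(f"need >=5 seed epochs for state {s.name}")
            centroids[s] = z[sel].mean(axis=0)
            emg_by_state[s] = emg_raw[sel]
        wake_thr, atonia_thr = _emg_thresholds(emg_by_state)
        return StateTemplateSet(animal_id, centroids, wake_thr, atonia_thr, center, scale)

    last_err: Exception | None = None
    weights = np.ones(z.shape[1])
    weights[_EMG_IDX] = _EMG_CLUSTER_WEIGHT
    for attempt in range(20):
        km = KMeans(n_clusters=4, n_init=20, random_state=random_state + attempt)
        assign = km.fit_predict(z * weights)
        counts = np.bincount(assign, minlength=4)
        if np.any(counts == 0):
            last_err = ValueError("empty cluster")
            continue
        try:
            cluster_means_raw = np.stack([x[assign == c].mean(axis=0) for c in range(4)])
            cluster_z = np.stack([z[assign == c].mean(axis=0) for c in range(4)])
            remaining = set(range(4))
            mapping: dict[State, int] = {}
            nrem = max(remaining, key=lambda c: cluster_means_raw[c, _DELTA_IDX])
            mapping[State.NREM] = nrem
            remaining.discard(nrem)
            wake = max(remaining, key=lambda c: cluster_means_raw[c, _EMG_IDX])
            mapping[State.WAKE] = wake
            remaining.discard(wake)
            a, b = sorted(remaining)
            # of the two theta-leaning clusters, REM is the atonic one
            rem, theta = (
                (a, b)
                if cluster_means_raw[a, _EMG_IDX] < cluster_means_raw[b, _EMG_IDX]
                else (b, a)
            )
            mapping[State.REM] = rem
            mapping[State.THETA_WAKE] = theta
            centroids = {s: cluster_z[c].copy() for s, c in mapping.items()}
            emg_by_state = {s: emg_raw[assign == c] for s, c in mapping.items()}
            wake_thr, atonia_thr = _emg_thresholds(emg_by_state)
            return StateTemplateSet(animal_id, centroids, wake_thr, atonia_thr, center, scale)
        except ValueError as err:  # degenerate centroids or thresholds
            last_err = err
            continue
    raise ValueError(f"could not fit non-degenerate templates after 20 restarts: {last_err}")


def _mean_ranks(z_epoch: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Mean over features of each state's closeness rank (1 = closest;
    ties share average ranks)."""
    dist = np.abs(centroids - z_epoch[None, :])  # (n_states, n_features)
    ranks = np.empty_like(dist)
    for j in range(dist.shape[1]):
        ranks[:, j] = rankdata(dist[:, j], method="average")
    return ranks.mean(axis=1)


def rank_membership_classify(epoch: EpochFeatures, templates: StateTemplateSet) -> State:
    """Classify one epoch by ranked membership with EMG overrides.

    Ties on mean rank break by smallest standardised Euclidean distance,
    then by the fixed order NREM, REM, THETA_WAKE, WAKE. Overrides: a REM
    call without atonia becomes THETA_WAKE; an atonic wake call with theta
    dominance (theta power > delta power) becomes REM.
    """
    if epoch.artefact:
        raise ValueError("refusing to classify an artefact epoch; mask it first")
    states = list(templates.centroids)
    z = templates.standardise(feature_matrix([epoch])[0])
    cent = np.stack([templates.centroids[s] for s in states])
    mean_rank = _mean_ranks(z, cent)
    best = mean_rank.min()
    tied = [s for s, r in zip(states, mean_rank) if r <= best + 1e-12]
    if len(tied) > 1:
        d2 = {s: float(np.sum((z - templates.centroids[s]) ** 2)) for s in tied}
        dbest = min(d2.values())
        tied = [s for s in tied if d2[s] <= dbest + 1e-12]
        if len(tied) > 1:
            tied = [s for s in TIEBREAK_ORDER if s in tied][:1]
    label = tied[0]
    emg = epoch.emg_rms
    if label == State.REM and emg > templates.emg_atonia_threshold:
        label = State.THETA_WAKE
    elif (
        label in (State.WAKE, State.THETA_WAKE)
        and emg < templates.emg_atonia_threshold
        and epoch.band_power["theta"] > epoch.band_power["delta"]
    ):
        label = State.REM
    return label


def score_recording(
    recording: Recording,
    templates: StateTemplateSet,
    *,
    features: Sequence[EpochFeatures] | None = None,
    artefact_mask: np.ndarray | None = None,
) -> Hypnogram:
    """Score every epoch of a recording against a template set.

    Artefact epochs (per ``artefact_mask`` or pre-set feature flags) are
    labelled ARTEFACT. No temporal smoothing is applied: scoring is per
    epoch, so permuting epochs permutes labels identically.
    """
    if features is None:
        features = extract_features(recording)
    labels = np.empty(len(features), dtype=np.int8)
    for i, f in enumerate(features):
        bad = f.artefact or (artefact_mask is not None and bool(artefact_mask[i]))
        if bad:
            labels[i] = int(State.ARTEFACT)
        else:
            labels[i] = int(rank_membership_classify(f, templates))
    return Hypnogram(
        labels=labels,
        epoch_seconds=recording.epoch_seconds,
        start_clock_time=recording.start_clock_time,
        schedule=recording.schedule,
    )
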