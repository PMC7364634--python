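"""Independent brute-force oracles used to validate the package's
vectorised implementations. These deliberately re-derive each operation
sample-by-sample / element-by-element and share no code with the package
internals beyond published constants of the operator definitions."""
from __future__ import annotations

from itertools import groupby

import numpy as np

from murisleep.states import State

MIN_HALFWAVE_SECONDS = 1.0 / 60.0  # 30 Hz analysis ceiling


def halfwave_oracle(epoch, fs, bands):
    """Sample-level zero-crossing enumeration of half-wave features."""
    x = [float(v) for v in epoch]
    n = len(x)
    mean = sum(x) / n
    y = [v - mean for v in x]
    pos = [v >= 0.0 for v in y]
    boundaries = []
    for i in range(1, n):
        if pos[i] != pos[i - 1]:
            boundaries.append(i)
    counts = {b.name: 0 for b in bands}
    sums = {b.name: 0.0 for b in bands}
    for k in range(len(boundaries) - 1):
        start, stop = boundaries[k], boundaries[k + 1]
        length = stop - start
        if length < MIN_HALFWAVE_SECONDS * fs:
            continue
        f = fs / (2.0 * length)
        peak = max(abs(v) for v in y[start:stop])
        for b in bands:
            if b.lo < f <= b.hi:
                counts[b.name] += 1
                sums[b.name] += peak
                break
    amps = {
        name: (sums[name] / counts[name] if counts[name] else 0.0) for name in counts
    }
    return counts, amps


def rle_bouts_oracle(labels, *, min_sleep_epochs=3):
    """Run-length-encoding re-derivation of bout detection.

    Returns a list of (kind, start, length) tuples in the same order as
    murisleep.metrics.detect_bouts (all SLEEP bouts, then all REM bouts).
    """
    labels = [int(v) for v in labels]
    out = []
    pos = 0
    runs = []
    for key, grp in groupby(labels):
        length = len(list(grp))
        runs.append((key, pos, length))
        pos += length
    # sleep runs: merge adjacent NREM/REM runs
    sleep_set = {int(State.NREM), int(State.REM)}
    i = 0
    while i < len(runs):
        if runs[i][0] in sleep_set:
            j = i
            while j < len(runs) and runs[j][0] in sleep_set:
                j += 1
            seg = runs[i:j]
            start = seg[0][1]
            total = sum(r[2] for r in seg)
            has_nrem3 = any(r[0] == int(State.NREM) and r[2] >= 3 for r in seg)
            has_rem2 = any(r[0] == int(State.REM) and r[2] >= 2 for r in seg)
            if total >= min_sleep_epochs and (has_nrem3 or has_rem2):
                out.append(("SLEEP", start, total))
            i = j
        else:
            i += 1
    for key, start, length in runs:
        if key == int(State.REM) and length >= 2:
            out.append(("REM", start, length))
    return out


def _avg_ranks(values):
    """Average ranks (1-based) with ties sharing the mean rank."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and values[order[j]] == values[order[i]]:
            j += 1
        avg = (i + 1 + j) / 2.0  # mean of positions i+1 .. j
        for k in range(i, j):
            ranks[order[k]] = avg
        i = j
    return ranks


def rank_classify_oracle(epoch, templates):
    """Materialise the full feature x state rank matrix and apply the same
    tie-break and EMG-override rules as the classifier."""
    from murisleep.sigproc import feature_matrix
    from murisleep.states import TIEBREAK_ORDER

    states = list(templates.centroids)
    z = templates.standardise(feature_matrix([epoch])[0])
    n_feat = len(z)
    mean_rank = {s: 0.0 for s in states}
    for j in range(n_feat):
        dists = [abs(z[j] - templates.centroids[s][j]) for s in states]
        ranks = _avg_ranks(dists)
        for s, r in zip(states, ranks):
            mean_rank[s] += r / n_feat
    best = min(mean_rank.values())
    tied = [s for s in states if mean_rank[s] <= best + 1e-12]
    if len(tied) > 1:
        d2 = {s: sum((z - templates.centroids[s]) ** 2) for s in tied}
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


def frame_motion_oracle(prev, cur, grey_delta_min=10):
    """Per-pixel double loop."""
    h, w = prev.shape
    count = 0
    for i in range(h):
        for j in range(w):
            if abs(int(cur[i, j]) - int(prev[i, j])) >= grey_delta_min:
                count += 1
    return count


def pink_noise_epoch(rng, n, fs, power=50.0):
    """Random 1/f-ish epoch for oracle tests."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    amp = np.zeros_like(freqs)
    sel = (freqs > 0.5) & (freqs <= 30.0)
    amp[sel] = 1.0 / np.sqrt(freqs[sel])
    spec = amp * np.exp(2j * np.pi * rng.random(len(freqs)))
    x = np.fft.irfft(spec * n / 2.0, n=n)
    return x * np.sqrt(power) / np.std(x)
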