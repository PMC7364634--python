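"""Inject clipping and flat-line artefacts, detect them, and apply the
week-level exclusion rule (a week is dropped when flagged epochs exceed 5%).
"""
import numpy as np

from murisleep import synth
from murisleep.hypnogram import Hypnogram
from murisleep.qc import apply_week_exclusion, flag_epochs
from murisleep.sigproc import epoch_split
from murisleep.states import State

hyp = Hypnogram(labels=np.full(100, int(State.WAKE)))
clean = synth.synthesize_signals(hyp, synth.default_state_specs(), fs=100.0, seed=3)

for n_bad, label in ((4, "4% artefacts"), (7, "7% artefacts")):
    clip = set(range(0, n_bad // 2))
    flat = set(range(50, 50 + n_bad - n_bad // 2))
    rec, truth_mask = synth.inject_artefacts(clean, clip_epochs=clip, flat_epochs=flat)
    eeg, *_ = epoch_split(rec)
    flags, reasons = flag_epochs(eeg, rec.fs)
    report = apply_week_exclusion(flags, reasons)
    hit = (flags == truth_mask).mean()
    print(
        f"{label}: flagged {report.artefact_fraction:5.1%} of epochs "
        f"(agreement with injected truth {100 * hit:.0f}%), "
        f"week excluded: {report.week_excluded}"
    )
print("\nThe 5% rule is strict: 5.0% flagged is retained, anything above is dropped.")
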