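"""Simulate a small longitudinal cohort and look at the generator truth.

Four treatment groups (WT, tTA, Tg, TgDOX) are observed every 4 weeks from
week 20 to 44. Only the Tg group progresses: EEG power declines 10% per
cycle after week 20, and dark-phase wake, REM fragmentation and home-cage
motion increase later.
"""
import numpy as np

from murisleep import synth

cohort = synth.CohortSpec(n_per_group=4, seed=1, hours_per_record=12.0)
dataset = synth.simulate_study(cohort)

truth = dataset.truth
dark = truth[truth.photoperiod == "DARK"]

print("Group-mean dark-phase NREM delta-band power (uV^2) by age:")
delta = dark[dark.outcome == "delta_power"].pivot_table(
    index="group", columns="age_week", values="value"
)
print(delta.round(1))
print()
print("Group-mean dark-phase wake (% of scorable epochs) by age:")
wake = dark[dark.outcome == "pct_wake"].pivot_table(
    index="group", columns="age_week", values="value"
)
print(wake.round(1))
print()
print("Terminal thickness (mm) per group:")
print(dataset.atrophy.groupby("group").thickness_mm.mean().round(2))
print()
print(
    "Reading: Tg delta power falls geometrically after week 20 "
    f"(week-44/week-20 ratio ~ {0.9**6:.2f}); Tg dark wake rises late; "
    "Tg thickness is reduced, and doxycycline (TgDOX) is protective."
)
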