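"""Turn a hypnogram into the study's architecture and continuity outcomes.

Sleep bouts need >= 3 consecutive NREM epochs or >= 2 consecutive REM
epochs inside a sleep run (and at least 30 s overall); REM bouts are REM
runs of >= 2 epochs (20 s). Percentages are split by photoperiod, and the
circadian amplitude is the light-minus-dark NREM difference.
"""
from murisleep import PhotoperiodSchedule, synth
from murisleep.metrics import (
    circadian_amplitude,
    detect_bouts,
    period_metrics,
    rem_episode_distribution,
)

schedule = PhotoperiodSchedule()
light, dark = synth.default_transition_matrices()
hyp = synth.simulate_hypnogram(schedule, light, dark, duration_hours=24, seed=5)

pm_light, pm_dark = period_metrics(hyp, animal_id="demo", group="WT", age_week=20)
for pm in (pm_light, pm_dark):
    print(
        f"{pm.photoperiod:>5}: wake {pm.pct_wake:5.1f}%  NREM {pm.pct_nrem:5.1f}%  "
        f"REM {pm.pct_rem:5.1f}%  sleep bouts {pm.sleep_bout_count:3.0f} "
        f"(mean {pm.sleep_bout_mean_len_s:5.0f} s)  REM bouts {pm.rem_bout_count:3.0f}"
    )
amp = circadian_amplitude(pm_light, pm_dark)
print(f"\nCircadian amplitude (light - dark NREM%): {amp:+.1f} points")
print("Mice sleep in the light phase, so the amplitude is positive.")

hist = rem_episode_distribution(hyp)
print(f"\nREM episode length histogram (epochs -> count): {dict(sorted(hist.items()))}")
n_bouts = sum(1 for b in detect_bouts(hyp) if b.kind == "REM")
print(f"REM episodes of >= 2 epochs qualify as bouts: {n_bouts} bouts today.")
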