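# murisleep

Rodent sleep-EEG analysis for longitudinal neurodegeneration studies, with a
synthetic cohort generator that makes every stage testable without any
recorded data.

The package implements the analysis chain of a home-cage polysomnography
study in a tauopathy mouse model (rTg4510-style design: wild-type, tTA
transactivator controls, tau transgenics, and doxycycline-suppressed
transgenics, observed every 4 weeks over 7 cycles):

- **Signal processing** (`murisleep.sigproc`) — zero-phase conditioning of
  differential EEG (1–300 Hz) and nuchal EMG (10–100 Hz), 10-s epochs, and
  per-epoch features: period–amplitude analysis (half-wave incidence and
  peak amplitude between baseline crossings, with equivalent frequency
  f = 1/(2·duration)), Welch band powers over δ (0.1–4 Hz), θ (5.1–9 Hz),
  α (9.1–12 Hz), β (12–20 Hz) and total (0.1–30 Hz), and EMG RMS.
- **Staging** (`murisleep.staging`) — per-animal state templates
  (individually optimised; labelled seeds or unsupervised k-means with
  semantic assignment) and ranked-membership classification of each epoch
  into wake, theta-dominated wake, NREM or REM, with EMG criteria: REM
  requires atonia, and an atonic theta-dominant "wake" call is re-labelled
  REM.
- **Architecture metrics** (`murisleep.metrics`) — sleep bouts (≥3
  consecutive NREM or ≥2 consecutive REM epochs inside a sleep run, 30 s
  minimum), REM bouts (≥2 epochs), time in state per light/dark period,
  REM episode length histograms, circadian amplitude (light−dark NREM%),
  weekly aggregation.
- **Quality control** (`murisleep.qc`) — clipping and flat-line detection
  per epoch, the strict ">5% of epochs" week-exclusion rule, and a
  low-amplitude flag for weeks where the EEG has collapsed below a fraction
  of baseline power.
- **Video locomotor activity** (`murisleep.video`) — frame differencing of
  720×480 greyscale video with an inclusive 10-grey-level per-pixel change
  threshold; per-photoperiod relative distance.
- **Longitudinal statistics** (`murisleep.stats`) — group×age cell-means
  (least-squares means) with an unstructured within-animal covariance,
  pairwise group contrasts at each age with Kramer standard errors and
  studentized-range adjustment jointly controlling the declared family
  (6 pairs × 7 ages = 42 contrasts), log-scale analysis with multiplicative
  back-transform, one-way ANOVA + Tukey HSD for terminal measures, and
  Spearman correlations against terminal atrophy on actual values or on
  within-group-centred residuals.
- **Synthetic cohorts** (`murisleep.synth`) — circadian-modulated Markov
  hypnograms, state-typical EEG/EMG spectra (1/f background plus
  band-limited oscillators; REM distinguished from theta-wake solely by
  EMG), epoch-aligned artefacts, home-cage video frames, progressive Tg
  phenotype and atrophy coupled to realised severity.

## Worked example

Stage one synthetic day and score it against the generator truth
(`examples/02_stage_a_recording.py`):

```
Epoch-wise agreement over 2160 epochs: 100.0%
EMG thresholds: wake > 2.00, atonia < 0.65 (a.u.)

Confusion (rows = truth, columns = scored):
                  WAKE  THETA_WAKE        NREM         REM
      WAKE         693           0           0           0
THETA_WAKE           0         141           0           0
      NREM           0           0        1101           0
       REM           0           0           0         225
```

With the default well-separated state spectra the ranked-membership stager
recovers every epoch; REM and theta-dominated wake share an EEG signature
and are separated by the EMG atonia threshold alone.

Running the longitudinal contrasts on a simulated cohort
(`examples/06_longitudinal_contrasts.py`) prints Tg-vs-WT NREM delta-power
ratios falling with age (to ≈ 0.9⁶ ≈ 0.53 of baseline by week 44), their
Tukey–Kramer-adjusted p values, a terminal-thickness ANOVA, and the
actual/residual atrophy correlations. The other `examples/` scripts cover
cohort simulation, architecture metrics, quality control, and video motion.

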