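# Methods

This note documents the models, numerical choices and limitations behind
`murisleep`: what the synthetic generator emulates, how each analysis stage
is defined where the field's conventions leave latitude, and what passing
tests do and do not establish about real recordings.

## Study design being modelled

Four treatment groups — wild type (WT), tTA transactivator-only controls,
tau transgenics (Tg) and doxycycline-suppressed transgenics (TgDOX) — are
recorded in the home cage under a 12:12 light/dark cycle, one week in every
4-week cycle, at ages 20, 24, 28, 32, 36, 40 and 44 weeks. Differential EEG
is acquired at 400 Hz (1–300 Hz), nuchal EMG at 10–100 Hz summarised as RMS
per 10-s epoch. Epochs are scored as wake, theta-dominated wake, NREM or
REM. Terminal atrophy enters as one number per animal (summed bilateral
hippocampus + cortex thickness, mm).

## Synthetic data generator

**Hypnograms.** Per-epoch states follow a first-order Markov chain with two
transition matrices, one per photoperiod phase; continuous circadian phase
modulation is deliberately not modelled — two matrices suffice to produce
the light/dark differences the metrics quantify. Baseline matrices use a
persistence construction (1−α)·I + α·1πᵀ whose stationary distribution is
exactly π (light: 30% wake, 5% theta-wake, 55% NREM, 10% REM, α = 0.15;
dark: 55/10/28/7, α = 0.20), giving NREM runs of a few minutes at 10-s
epochs.

**Signals.** Each epoch's EEG is a sum of equal-power random-phase
oscillations on the epoch's Fourier grid: a 1/f background (default
5 µV² total over 0.1–30 Hz) plus per-band components sized so the
band-integrated power equals the state's target (background share
subtracted, floored at zero). Because the oscillation frequencies are
harmonics of the 0.1 Hz epoch grid, each epoch's realised band power equals
the target exactly up to estimator error — this is what makes the ±20%
calibration checks sharp. Default state targets (µV², δ/θ/α/β): wake
40/40/25/20, theta-wake 20/120/12/6, NREM 200/40/15/8, REM 20/120/12/6.
NREM has the maximal delta target; REM and theta-wake are spectrally
identical and differ only in EMG tone (0.3 vs 3.0 a.u.; wake 3.5, NREM
1.0), so REM detection must run through the atonia criterion, as in the
modelled assay. "Theta-dominated wake" has no published spectral
definition; wake-level EMG with theta-band EEG is an assumption. EMG is
white noise normalised to the state's RMS exactly. An optional
`sensor_noise` adds an amplitude-independent white floor; it is the
mechanism by which staging degrades as EEG amplitude collapses (the
late-stage Tg regime), and is off by default.

**Progressive phenotype.** Trajectories are per-group. Tg defaults: power
declines ×0.90 per cycle after week 20 (amplitude scales by the square
root); dark-phase stationary wake rises 2 percentage points per cycle; the
REM continuation probability is multiplied by 0.80 per cycle (REM episodes
collapse toward 1-epoch fragments); home-cage motion rises 15% per cycle.
The architecture changes (wake, fragmentation, motion) start 12 weeks after
the spectral onset (`architecture_lag_weeks`): the modelled phenotype has
spectral decline preceding sleep-architecture change, and a shared onset
would make the two first-detected at the same age. WT, tTA and TgDOX have
flat trajectories (doxycycline suppression). Fragmentation is applied
before the wake adjustment, and the wake adjustment bisects a blend weight
(toward all-wake or all-NREM) until the stationary wake fraction hits the
target, so `dark_wake_increase` is the realised points-per-cycle change.
Between-animal heterogeneity: a lognormal amplitude baseline (σ = 0.10 on
log amplitude, hence σ ≈ 0.2 on log power) and a per-animal wake offset
(σ = 2 points), both constant across ages so the within-animal covariance
is informative.

**Atrophy.** thickness = group mean + coupling × (within-group standardised
final dark-phase NREM%) + N(0, group SD). Group means (mm): WT 3.20,
tTA 3.00, TgDOX 3.00, Tg 2.50; coupling 0.05 mm/SD. Group separation drives
the pooled "actual" correlation; the coupling term drives the within-group
"residual" correlation, so both behaviours of the correlation analysis can
be dialled independently.

**Video.** Greyscale frames (default 480×720) with a 20×20 block on a
uniform background (grey 140 on 100, a 40-level step) that displaces
horizontally by round(intensity) pixels per frame, so the changed-pixel
count is 2·h·min(d, w) — monotone in the frame's motion intensity, zero
when still. Position wraps on a long track; traces long enough to wrap see
one inflated count at the wrap.

**Artefacts.** Epoch-aligned only, matching the epoch granularity of QC:
clipping rescales the epoch so ≥15% of samples sit at the rail then
saturates; flat-lining replaces the epoch with its mean.

All generators are pure functions of (spec, seed); study-level seeds are
spawned per animal×week from the cohort seed.

## Signal processing

Welch band power uses 2-s Hann windows with 50% overlap within the 10-s
epoch (0.5 Hz bins, 9 segments) and integrates the PSD over half-open bands
(lo, hi], so the printed gaps (4–5.1, 9–9.1 Hz) belong to no named band and
the named-band sum is bounded by total power by construction. Conditioning
is a 4th-order Butterworth applied forward–backward (zero phase, so
half-wave timing is undistorted); the nominal acquisition band is honoured
up to 0.95× Nyquist of the working rate with a logged warning (at the
100 Hz fast rate the effective ceiling is 47.5 Hz). Half-waves are
delimited by crossings of the epoch-mean baseline with no hysteresis; a
minimum duration of 1/60 s (the 30 Hz analysis ceiling) suppresses
sample-noise crossings. The half-wave operator is a conventional
period–amplitude definition, implemented identically in a vectorised path
and a brute-force oracle used by the tests.

## Staging

The published system's exact feature set and ranking statistic are
proprietary; this module is a reproducible stand-in with the same contract,
not a replica. Features per epoch: 4 band powers, total power, 4 half-wave
counts, 4 half-wave mean amplitudes, EMG RMS (14 features), standardised
per recording week. Ranked membership: per feature, states are ranked by
|z − centroid| (average ranks on ties); the smallest mean rank wins; ties
break by standardised Euclidean distance, then the fixed order NREM, REM,
THETA_WAKE, WAKE. EMG overrides run after ranking. Because every feature
scales by a positive constant under an EEG gain change, standardisation
makes the classifier scale-invariant once templates are refit — mirroring
per-week template re-optimisation. Unsupervised template fitting runs
k-means (k = 4, 20 restarts, fixed seed) with the EMG dimension up-weighted
×4, because REM and theta-wake are separable only on that axis; clusters
are then assigned semantically (max delta → NREM, max EMG of the rest →
WAKE, the atonic one of the remaining pair → REM). EMG thresholds sit at
midpoints between state-wise EMG medians. No temporal smoothing is applied
(scoring is per-epoch and order-independent); a 3-epoch majority filter
exists behind a flag, default off.

## Architecture metrics

A maximal sleep run (NREM/REM, artefacts break runs) is a sleep bout when
it contains ≥3 consecutive NREM epochs or ≥2 consecutive REM epochs and
spans ≥3 epochs overall, so the minimal sleep bout is 30 s and the minimal
REM bout 20 s. The run-length minimum is a deliberate resolution of an
ambiguity: whether an isolated 2-epoch REM run embedded in wake counts as a
20-s "sleep bout" is unclear under the stated rules; the default says no
(keeping the 30-s sleep-bout floor), and `min_sleep_epochs=2` restores the
permissive reading. An NREM-only bout mode exists behind `nrem_only`.
Percentages use scorable (non-artefact) epochs as denominator so exclusions
do not deflate state time; theta-dominated wake is reported merged into
wake, while 4-state labels are preserved in hypnogram files.

## Quality control

Thresholds are not published; defaults (rail fraction 0.98 with ≥1% of
samples in runs of ≥5, flat variance floor 10⁻³ µV² over 2-s windows,
low-amplitude floor 20% of the first-week median total power) were chosen
to separate the generator's artefacts from clean synthetic EEG exactly, and
are config-exposed. Week exclusion is strict: a week is dropped only when
the flagged fraction exceeds 5%. The published study used expert visual
review; these automated rules are a stand-in.

## Longitudinal statistics

The repeated-measures model is a cell-means (profile) fit: least-squares
means are group×age cell means, and the within-animal covariance across
ages is pooled from residual cross-products, pairwise-complete over missing
weeks (df per pair = complete pairs − number of groups), with a
compound-symmetry fallback if the estimate degenerates. No iterative
mixed-model likelihood is used: the estimator is deterministic and matches
the unstructured-covariance, LS-means reporting convention. Contrasts use
Kramer's unequal-n standard error from the age's pooled variance,
t = |Δ|/SE, q = t·√2, and the studentized-range distribution with
k = number of groups; the default family jointly controls all pairs × ages
(Bonferroni factor across ages on the per-age Tukey p), which a 500-replicate
global-null simulation calibrates to a family-wise error near 0.05 (the
per-age-only mode is available and controls each age at nominal level).
With 2 groups and 1 age the adjusted p collapses to the two-sided t-test p.
Log-scale outcomes are back-transformed to ratios with simultaneous
intervals from the same studentized-range quantile. "Spearman residuals"
are interpreted as rank correlation of within-group mean-centred values —
the paper-style actual/residual dissociation (group-shift-only data gives
strong actual and near-zero residual correlation) follows from this
definition; p values use the t approximation, or a seeded permutation null
below n = 12. An additive blocking covariate for experiment location is
supported for open-field outcomes, default off.

## Problem sizes and what the tests show

Heavy checks run at sizes chosen for a single CPU: staging recovery on one
24-h day at 100 Hz (8,640 epochs; all spectral code is rate-agnostic, 400 Hz
is simply slower), effect recovery on n = 15/group × 7 ages with 24-h truth
hypnograms and 0.5 h of synthesized signal per animal-week for measured
NREM delta power (architecture outcomes come from the truth hypnograms;
staging fidelity is established separately by the recovery check), and 500
replicates for the family-wise-error simulation. The generator produces
well-separated state spectra, stationary within-state statistics, and
exactly epoch-aligned artefacts; real recordings have drifting spectra,
state transitions inside epochs, movement artefacts of every shape, and
electrode degradation. Passing tests therefore establish the internal
consistency and statistical calibration of the pipeline, not field
performance on real EEG. The in-vivo results of any particular study
(group curves, F statistics, correlation coefficients) are not reproduced
here — no such data ship with the package.
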