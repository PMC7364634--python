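import numpy as np
import pytest

from murisleep import PhotoperiodSchedule, synth
from murisleep.bands import DEFAULT_BANDS, TOTAL
from murisleep.sigproc import band_power, emg_rms
from murisleep.states import State


class TestPhotoperiodSchedule:
    def test_invalid_hours_rejected(self):
        with pytest.raises(ValueError):
            PhotoperiodSchedule(light_hours=13.0, dark_hours=12.0)

    def test_phase_lookup(self, schedule):
        assert schedule.phase_at(6.0) == "LIGHT"
        assert schedule.phase_at(18.0) == "DARK"
        assert schedule.phase_at(5.99) == "DARK"


class TestSimulateHypnogram:
    def test_degenerate_chain_all_wake(self, schedule):
        m = np.zeros((4, 4))
        m[:, 0] = 1.0  # all mass on WAKE
        h = synth.simulate_hypnogram(schedule, m, m, duration_hours=12, seed=0)
        assert (h.labels == int(State.WAKE)).all()

    def test_same_seed_bitwise_identical(self, schedule):
        light, dark = synth.default_transition_matrices()
        h1 = synth.simulate_hypnogram(schedule, light, dark, duration_hours=6, seed=42)
        h2 = synth.simulate_hypnogram(schedule, light, dark, duration_hours=6, seed=42)
        assert np.array_equal(h1.labels, h2.labels)

    def test_ergodic_chain_matches_stationary_distribution(self, schedule):
        # rows equal to the target distribution: stationary by construction,
        # cross-checked by eigen-analysis
        pi_target = np.array([0.3, 0.1, 0.5, 0.1])  # WAKE, THETA, NREM, REM
        m = np.tile(pi_target, (4, 1))
        pi = synth.stationary_distribution(m)
        assert pi == pytest.approx(pi_target, abs=1e-12)
        h = synth.simulate_hypnogram(schedule, m, m, duration_hours=168, seed=7)
        for s, target in zip((State.WAKE, State.THETA_WAKE, State.NREM, State.REM), pi_target):
            frac = (h.labels == int(s)).mean()
            assert frac == pytest.approx(target, abs=0.02)

    def test_non_stochastic_matrix_rejected(self, schedule):
        bad = np.full((4, 4), 0.3)
        with pytest.raises(ValueError, match="stochastic"):
            synth.simulate_hypnogram(schedule, bad, bad, duration_hours=1, seed=0)

    def test_duration_must_be_epoch_multiple(self, schedule):
        light, dark = synth.default_transition_matrices()
        with pytest.raises(ValueError, match="multiple"):
            synth.simulate_hypnogram(schedule, light, dark, duration_hours=0.0014, seed=0)

    def test_empirical_transitions_converge_to_matrix(self, schedule):
        light, dark = synth.default_transition_matrices()
        h = synth.simulate_hypnogram(
            schedule, light, light, duration_hours=10000 * 10 / 3600.0, seed=5
        )
        idx = {int(s): i for i, s in enumerate((State.WAKE, State.THETA_WAKE, State.NREM, State.REM))}
        counts = np.zeros((4, 4))
        lab = h.labels
        for a, b in zip(lab[:-1], lab[1:]):
            counts[idx[int(a)], idx[int(b)]] += 1
        emp = counts / counts.sum(axis=1, keepdims=True)
        tv = 0.5 * np.abs(emp - light).sum(axis=1)
        assert (tv < 0.05).all()


class TestSynthesizeSignals:
    def test_band_power_calibration(self, schedule, state_specs):
        from murisleep import Hypnogram

        hyp = Hypnogram(labels=np.full(30, int(State.NREM)), schedule=schedule)
        rec = synth.synthesize_signals(hyp, state_specs, fs=100.0, seed=1)
        spe = rec.samples_per_epoch
        measured = {b.name: [] for b in DEFAULT_BANDS}
        for i in range(30):
            ep = rec.eeg[i * spe : (i + 1) * spe]
            for b in DEFAULT_BANDS:
                measured[b.name].append(band_power(ep, 100.0, b))
        targets = state_specs[State.NREM].band_power_targets
        for name, target in targets.items():
            assert np.mean(measured[name]) == pytest.approx(target, rel=0.20)

    def test_strong_delta_target_recovered(self, schedule):
        from murisleep import Hypnogram

        spec = synth.StateSpectrumSpec(
            State.NREM,
            {"delta": 100.0, "theta": 1.0, "alpha": 1.0, "beta": 1.0},
            emg_tone=1.0,
            background_power=0.0,
        )
        hyp = Hypnogram(labels=np.full(30, int(State.NREM)), schedule=schedule)
        rec = synth.synthesize_signals(hyp, {State.NREM: spec}, fs=100.0, seed=2)
        spe = rec.samples_per_epoch
        vals = [
            band_power(rec.eeg[i * spe : (i + 1) * spe], 100.0, DEFAULT_BANDS[0])
            for i in range(30)
        ]
        assert np.mean(vals) == pytest.approx(100.0, rel=0.20)

    def test_all_zero_targets_silent(self, schedule):
        from murisleep import Hypnogram

        spec = synth.StateSpectrumSpec(
            State.WAKE,
            {"delta": 0.0, "theta": 0.0, "alpha": 0.0, "beta": 0.0},
            emg_tone=0.0,
            background_power=0.0,
        )
        hyp = Hypnogram(labels=np.full(5, int(State.WAKE)), schedule=schedule)
        rec = synth.synthesize_signals(hyp, {State.WAKE: spec}, fs=100.0, seed=3)
        assert np.allclose(rec.eeg, 0.0)
        assert np.allclose(rec.emg, 0.0)

    def test_amplitude_scale_squares_into_power(self, schedule, state_specs):
        from murisleep import Hypnogram

        hyp = Hypnogram(labels=np.full(10, int(State.NREM)), schedule=schedule)
        rec1 = synth.synthesize_signals(hyp, state_specs, fs=100.0, seed=4)
        half = {s: sp.scaled(0.5) for s, sp in state_specs.items()}
        rec2 = synth.synthesize_signals(hyp, half, fs=100.0, seed=4)
        spe = rec1.samples_per_epoch
        for i in range(10):
            p1 = band_power(rec1.eeg[i * spe : (i + 1) * spe], 100.0, TOTAL)
            p2 = band_power(rec2.eeg[i * spe : (i + 1) * spe], 100.0, TOTAL)
            assert p2 == pytest.approx(0.25 * p1, rel=1e-6)

    def test_emg_tone_realised_exactly(self, schedule, state_specs):
        from murisleep import Hypnogram

        hyp = Hypnogram(labels=np.full(8, int(State.REM)), schedule=schedule)
        rec = synth.synthesize_signals(hyp, state_specs, fs=100.0, seed=5)
        spe = rec.samples_per_epoch
        for i in range(8):
            assert emg_rms(rec.emg[i * spe : (i + 1) * spe]) == pytest.approx(
                state_specs[State.REM].emg_tone, rel=1e-9
            )

    def test_missing_state_spec_rejected(self, schedule, state_specs):
        from murisleep import Hypnogram

        hyp = Hypnogram(labels=np.array([int(State.WAKE), int(State.REM)]), schedule=schedule)
        with pytest.raises(ValueError, match="REM"):
            synth.synthesize_signals(hyp, {State.WAKE: state_specs[State.WAKE]}, fs=100.0, seed=0)


class TestInjectArtefacts:
    def _recording(self, schedule, state_specs, n_epochs=20):
        from murisleep import Hypnogram

        hyp = Hypnogram(labels=np.full(n_epochs, int(State.WAKE)), schedule=schedule)
        return synth.synthesize_signals(hyp, state_specs, fs=100.0, seed=6)

    def test_no_artefacts_identity(self, schedule, state_specs):
        rec = self._recording(schedule, state_specs)
        out, mask = synth.inject_artefacts(rec)
        assert np.array_equal(out.eeg, rec.eeg)
        assert not mask.any()

    def test_flat_epoch_zero_variance(self, schedule, state_specs):
        rec = self._recording(schedule, state_specs)
        out, mask = synth.inject_artefacts(rec, flat_epochs={5})
        spe = rec.samples_per_epoch
        assert np.var(out.eeg[5 * spe : 6 * spe]) == pytest.approx(0.0, abs=1e-24)
        assert mask[5] and mask.sum() == 1

    def test_clip_epoch_saturates(self, schedule, state_specs):
        rec = self._recording(schedule, state_specs)
        out, _ = synth.inject_artefacts(rec, clip_epochs={3}, rail=150.0)
        spe = rec.samples_per_epoch
        block = out.eeg[3 * spe : 4 * spe]
        assert (np.abs(block) >= 150.0 - 1e-9).mean() >= 0.10
        assert np.abs(block).max() <= 150.0 + 1e-9

    def test_untouched_epochs_identical(self, schedule, state_specs):
        rec = self._recording(schedule, state_specs)
        out, _ = synth.inject_artefacts(rec, clip_epochs={3}, flat_epochs={5})
        spe = rec.samples_per_epoch
        keep = np.ones(rec.n_samples, dtype=bool)
        keep[3 * spe : 4 * spe] = False
        keep[5 * spe : 6 * spe] = False
        assert np.array_equal(out.eeg[keep], rec.eeg[keep])

    def test_overlapping_sets_rejected(self, schedule, state_specs):
        rec = self._recording(schedule, state_specs)
        with pytest.raises(ValueError, match="disjoint"):
            synth.inject_artefacts(rec, clip_epochs={1}, flat_epochs={1})


class TestSimulateStudy:
    @pytest.fixture(scope="class")
    def small_study(self):
        cohort = synth.CohortSpec(n_per_group=4, ages=(20.0, 32.0, 44.0), seed=77)
        return synth.simulate_study(cohort)

    def test_determinism(self):
        cohort = synth.CohortSpec(n_per_group=2, ages=(20.0, 44.0), seed=5, hours_per_record=2.0)
        d1 = synth.simulate_study(cohort)
        d2 = synth.simulate_study(cohort)
        assert d1.truth.equals(d2.truth)
        assert d1.atrophy.equals(d2.atrophy)
        for key in d1.hypnograms:
            assert np.array_equal(d1.hypnograms[key].labels, d2.hypnograms[key].labels)

    def test_missing_trajectory_rejected(self):
        cohort = synth.CohortSpec(n_per_group=2, ages=(20.0, 24.0), seed=1, hours_per_record=1.0)
        with pytest.raises(ValueError, match="Tg"):
            synth.simulate_study(cohort, {"WT": synth.TrajectorySpec("WT")})

    def test_null_trajectories_have_no_age_trend(self):
        from scipy.stats import linregress

        cohort = synth.CohortSpec(n_per_group=6, ages=(20.0, 28.0, 36.0, 44.0), seed=21,
                                  hours_per_record=6.0)
        null = {g: synth.TrajectorySpec(g) for g in cohort.groups}
        ds = synth.simulate_study(cohort, null)
        power = ds.truth[(ds.truth.outcome == "total_power") & (ds.truth.photoperiod == "LIGHT")]
        res = linregress(power.age_week, power.value)
        assert abs(res.slope) < 2 * res.stderr + 1e-12

    def test_tg_amplitude_declines_geometrically(self, small_study):
        # power declines 10%/cycle after week 20 -> week-44 power scale
        # (0.9)^6 times the week-20 value, i.e. amplitude scale (0.9)^3
        s = small_study.scales
        tg = s[s.group == "Tg"]
        for animal in tg.animal_id.unique():
            a20 = tg[(tg.animal_id == animal) & (tg.age_week == 20.0)].amplitude_scale.iloc[0]
            a44 = tg[(tg.animal_id == animal) & (tg.age_week == 44.0)].amplitude_scale.iloc[0]
            assert (a44 / a20) ** 2 == pytest.approx(0.9**6, rel=1e-9)

    def test_tg_measured_delta_power_follows_decline(self, small_study):
        # pipeline-measured delta power at week 44 vs 20, one Tg animal
        from murisleep.bands import DELTA

        animal = "Tg-00"
        vals = {}
        for week in (20.0, 44.0):
            rec = small_study.recording(animal, week, hours=1.0)
            hyp = small_study.hypnograms[(animal, week)]
            spe = rec.samples_per_epoch
            powers = [
                band_power(rec.eeg[i * spe : (i + 1) * spe], rec.fs, DELTA)
                for i in range(rec.n_epochs)
                if hyp.labels[i] == int(State.NREM)  # NREM-restricted delta
            ]
            vals[week] = np.mean(powers)
        assert vals[44.0] / vals[20.0] == pytest.approx(0.9**6, rel=0.10)

    def test_tg_dark_wake_and_fragmentation_progress(self, small_study):
        truth = small_study.truth
        dark = truth[truth.photoperiod == "DARK"]

        def group_mean(group, outcome, week):
            sel = dark[(dark.group == group) & (dark.outcome == outcome) & (dark.age_week == week)]
            return sel.value.mean()

        assert group_mean("Tg", "pct_wake", 44.0) > group_mean("Tg", "pct_wake", 20.0) + 5
        assert group_mean("WT", "pct_wake", 44.0) == pytest.approx(
            group_mean("WT", "pct_wake", 20.0), abs=5.0
        )
        assert group_mean("Tg", "rem_bout_count", 44.0) < group_mean("Tg", "rem_bout_count", 20.0)
        assert group_mean("Tg", "motion", 44.0) > group_mean("Tg", "motion", 20.0)

    def test_rem_fragmentation_majority_single_epoch(self, small_study):
        from murisleep.metrics import rem_episode_distribution

        hist: dict[int, int] = {}
        for (animal, week), hyp in small_study.hypnograms.items():
            if animal.startswith("Tg-") and week == 44.0:
                for k, v in rem_episode_distribution(hyp).items():
                    hist[k] = hist.get(k, 0) + v
        total = sum(hist.values())
        assert hist.get(1, 0) / total > 0.5  # majority of REM episodes 1 epoch long

    def test_atrophy_couples_to_final_nrem(self, small_study):
        from murisleep.stats import correlate_with_atrophy

        truth = small_study.truth
        final = truth[
            (truth.photoperiod == "DARK")
            & (truth.outcome == "pct_nrem")
            & (truth.age_week == 44.0)
        ].set_index("animal_id")
        atr = small_study.atrophy.set_index("animal_id").loc[final.index]
        res = correlate_with_atrophy(final.value.to_numpy(), atr.thickness_mm.to_numpy())
        assert res.rs > 0
        assert res.p < 0.05


class TestSynthesizeVideo:
    def test_zero_trace_identical_frames(self):
        frames = synth.synthesize_video(np.zeros(5), frame_shape=(60, 90), seed=0)
        for t in range(1, 5):
            assert np.array_equal(frames[t], frames[t - 1])

    def test_same_seed_identical_frames(self):
        tr = np.array([0.0, 3.0, 7.0, 0.0])
        f1 = synth.synthesize_video(tr, frame_shape=(60, 90), seed=4)
        f2 = synth.synthesize_video(tr, frame_shape=(60, 90), seed=4)
        assert np.array_equal(f1, f2)

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            synth.synthesize_video(np.array([-1.0]), frame_shape=(60, 90), seed=0)

    def test_single_active_frame_changes_block_pixels(self):
        from murisleep.video import frame_motion

        trace = np.array([0.0, 20.0, 0.0])
        frames = synth.synthesize_video(trace, frame_shape=(480, 720), seed=1)
        assert frame_motion(frames[0], frames[1]) >= 400
        assert frame_motion(frames[1], frames[2]) == 0
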