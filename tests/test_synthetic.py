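"""Generator fidelity: spectra, kinematics and cohort structure."""

import numpy as np
import pytest

import gaitdecode as gd
from gaitdecode.errors import InvalidArgumentError
from gaitdecode.kinematics import StatusSegment
from gaitdecode.synthetic import (CohortConfig, TrialPlan,
                                  default_effect_profiles, simulate_cohort,
                                  simulate_kinematics,
                                  simulate_status_recording)


class TestAperiodicSignal:
    def test_zero_exponent_gives_flat_unit_psd(self):
        x = gd.simulate_aperiodic_signal(60, 2000, offset=0.0, exponent=0.0,
                                         seed=3)
        spec = gd.welch_psd(x, 2000)
        band = (spec.freqs >= 2) & (spec.freqs <= 200)
        assert np.abs(np.log10(spec.psd[band].mean())) < 0.05

    def test_loglog_regression_recovers_target_power_law(self):
        x = gd.simulate_aperiodic_signal(60, 2000, offset=1.5, exponent=2.0,
                                         seed=11)
        spec = gd.welch_psd(x, 2000)
        m = (spec.freqs >= 2) & (spec.freqs <= 95)
        slope, intercept = np.polyfit(np.log10(spec.freqs[m]),
                                      np.log10(spec.psd[m]), 1)
        assert slope == pytest.approx(-2.0, abs=0.1)
        assert intercept == pytest.approx(1.5, abs=0.1)

    def test_zero_mean_and_seed_determinism(self):
        a = gd.simulate_aperiodic_signal(10, 1000, 0.5, 1.0, seed=5)
        b = gd.simulate_aperiodic_signal(10, 1000, 0.5, 1.0, seed=5)
        assert a.mean() == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("duration,fs", [(0, 100), (-1, 100), (10, 0)])
    def test_nonpositive_duration_or_fs_rejected(self, duration, fs):
        with pytest.raises(InvalidArgumentError):
            gd.simulate_aperiodic_signal(duration, fs, 0.0, 1.0)


class TestStatusRecording:
    def test_unknown_region_rejected(self):
        segs = [StatusSegment("walking", 0, 10)]
        with pytest.raises(InvalidArgumentError):
            simulate_status_recording(segs, layout={"E": ["cortex"]})

    def test_empty_profile_has_no_periodic_power(self):
        segs = [StatusSegment("standing", 0, 60)]
        rec, _ = simulate_status_recording(segs, profiles=[],
                                           line_noise_amp=0.0, seed=21)
        model = gd.fit_spectral_model(gd.welch_psd(rec.data[5], rec.fs))
        powers = gd.band_power_table(model)
        assert all(v < 0.4 for v in powers.values())

    def test_beta_power_higher_standing_than_walking(self):
        # directional effect survives the full measurement chain
        wins = 0
        for seed in range(10):
            segs = [StatusSegment("standing", 0, 20),
                    StatusSegment("walking", 20, 40)]
            rec, _ = simulate_status_recording(segs, seed=seed)
            bp = gd.bipolar_montage(gd.notch_and_bandpass(rec))
            spl = bp.regions.index("SPL")
            vals = {}
            for lab, (a, b) in [("standing", (0, 20)), ("walking", (20, 40))]:
                x = bp.data[spl, int(a * rec.fs):int(b * rec.fs)]
                spec = gd.welch_psd(x, rec.fs)
                corr = np.maximum(
                    gd.preprocess.filter_power_response(spec.freqs, rec.fs),
                    1e-8)
                spec.psd = spec.psd / corr
                model = gd.fit_spectral_model(spec)
                vals[lab] = gd.periodic_band_power(model, "all_beta")
            wins += vals["standing"] > vals["walking"]
        assert wins >= 9

    def test_artifact_segment_flagged_by_aperiodic_rule(self):
        rest_segs = [StatusSegment("standing", 0, 30)]
        walk_segs = [StatusSegment("walking", 0, 30)]
        rest, _ = simulate_status_recording(rest_segs, profiles=[],
                                            line_noise_amp=0.0, seed=4)
        walk, _ = simulate_status_recording(
            walk_segs, profiles=[], line_noise_amp=0.0, seed=4,
            artifact_segments=[(0.0, 30.0, 2.0)])
        rest_m = gd.fit_spectral_model(gd.welch_psd(rest.data[0], rest.fs))
        walk_m = gd.fit_spectral_model(gd.welch_psd(walk.data[0], walk.fs))
        flagged, ratio = gd.flag_gait_artifact(walk_m, rest_m)
        assert flagged and ratio > 0.5


class TestKinematics:
    def test_constant_speed_path_length(self):
        trace, truth = simulate_kinematics(
            TrialPlan(duration=10.0, speed=1.0), fs=100, seed=1)
        assert truth["path_length_m"] == pytest.approx(10.0, abs=0.1)
        waist = trace.markers[("L", "waist")]
        assert (waist[-1, 1] - waist[0, 1]) / 1000.0 == pytest.approx(
            truth["path_length_m"], rel=0.01)

    def test_sampling_rate_invariance_of_speed(self):
        plan = TrialPlan(duration=20.0, speed=1.1)
        _, t100 = simulate_kinematics(plan, fs=100, seed=2)
        _, t200 = simulate_kinematics(plan, fs=200, seed=2)
        assert t100["average_speed"] == pytest.approx(
            t200["average_speed"], rel=0.01)

    def test_freeze_interval_power_concentrated_in_freeze_band(self):
        plan = TrialPlan(duration=20.0, speed=1.0,
                         freeze_intervals=[(8.0, 14.0)])
        trace, _ = simulate_kinematics(plan, fs=100, seed=3)
        z = trace.markers[("L", "foot")][:, 2]
        seg = z[int(9.0 * 100):int(13.0 * 100)]  # interior of the freeze
        seg = seg - seg.mean()
        freqs = np.fft.rfftfreq(seg.size, 0.01)
        power = np.abs(np.fft.rfft(seg * np.hanning(seg.size))) ** 2
        in_band = power[(freqs >= 3) & (freqs <= 8)].sum()
        assert in_band / power[freqs > 0].sum() >= 0.8

    def test_overlapping_freeze_intervals_rejected(self):
        with pytest.raises(InvalidArgumentError):
            TrialPlan(duration=20.0, freeze_intervals=[(2, 6), (5, 9)])


class TestCohort:
    def test_same_config_and_seed_identical(self):
        cfg = CohortConfig(n_subjects=1, med_states=("Moff",),
                           trials_per_status={"walking": 1},
                           sit_duration=8, stand_duration=8, gait_duration=8)
        a = simulate_cohort(cfg, seed=9)
        b = simulate_cohort(cfg, seed=9)
        for ta, tb in zip(a.trials, b.trials):
            np.testing.assert_array_equal(ta.recording.data,
                                          tb.recording.data)
            for key in ta.kinematics.markers:
                np.testing.assert_array_equal(ta.kinematics.markers[key],
                                              tb.kinematics.markers[key])

    def test_no_freeze_trials_gives_four_class_study(self):
        cfg = CohortConfig(n_subjects=2, med_states=("Moff",),
                           trials_per_status={"walking": 1, "dual_task": 1,
                                              "freezing": 0},
                           signals=False)
        study = simulate_cohort(cfg, seed=2)
        labels = {s.label for t in study.trials for s in t.true_segments}
        assert "freeze" not in labels
        assert {"sitting", "standing", "walking", "dual_task"} <= labels

    def test_invalid_subject_count_rejected(self):
        with pytest.raises(InvalidArgumentError):
            CohortConfig(n_subjects=0)

    def test_duplicate_region_band_profile_rejected(self):
        p = default_effect_profiles()
        with pytest.raises(InvalidArgumentError):
            CohortConfig(profiles=p + [p[0]])

    def test_segments_tile_each_trial(self, small_study):
        for t in small_study.trials:
            segs = sorted(t.true_segments, key=lambda s: s.start)
            assert segs[0].start == 0.0
            for a, b in zip(segs[:-1], segs[1:]):
                assert a.end == pytest.approx(b.start)

    def test_speed_beta_ground_truth_follows_configured_coupling(self):
        # speed = intercept + coupling * beta + noise, per design
        cfg = CohortConfig(n_subjects=8, med_states=("Moff",),
                           trials_per_status={"walking": 6},
                           subject_speed_sd=0.0, signals=False)
        study = simulate_cohort(cfg, seed=13)
        rows = [(t.true_spl_beta, t.true_speed)
                for t in study.gait_trials("Moff")]
        beta, speed = map(np.asarray, zip(*rows))
        slope = np.polyfit(beta, speed, 1)[0]
        assert slope == pytest.approx(cfg.speed_beta_coupling, abs=0.12)
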