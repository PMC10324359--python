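"""Walking speed, freezing index and status segmentation."""

import numpy as np
import pytest

from gaitdecode.errors import (InsufficientDataError, InvalidArgumentError,
                               MissingChannelError)
from gaitdecode.kinematics import (IFOG_CHANNELS, FreezingIndexSeries,
                                   KinematicTrace, SpeedSeries, StatusSegment,
                                   delta_speed, freezing_index,
                                   instantaneous_speed, segment_statuses)
from gaitdecode.synthetic import TrialPlan, simulate_kinematics


def _trace_from_z(z: np.ndarray, fs: float = 100.0,
                  channels=IFOG_CHANNELS) -> KinematicTrace:
    markers = {key: np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
               for key in channels}
    return KinematicTrace(fs=fs, markers=markers)


def _fft_band_ratio(z: np.ndarray, fs: float) -> float:
    """Independent freeze/locomotion power ratio on one Hann-tapered window."""
    z = z - np.polyval(np.polyfit(np.arange(z.size), z, 1), np.arange(z.size))
    power = np.abs(np.fft.rfft(z * np.hanning(z.size))) ** 2
    f = np.fft.rfftfreq(z.size, 1.0 / fs)
    return power[(f >= 3) & (f <= 8)].sum() / power[(f > 0) & (f < 3)].sum()


class TestSpeed:
    def test_constant_velocity(self):
        n = 500
        pos = np.column_stack([np.zeros(n), 10.0 * np.arange(n), np.zeros(n)])
        trace = KinematicTrace(fs=100.0, markers={("L", "waist"): pos})
        sp = instantaneous_speed(trace)
        assert np.allclose(sp.speed, 1.0)
        assert sp.average == pytest.approx(1.0)

    def test_stationary_marker(self):
        pos = np.zeros((300, 3))
        trace = KinematicTrace(fs=100.0, markers={("R", "waist"): pos})
        assert instantaneous_speed(trace).average == 0.0

    def test_commanded_speed_recovered_from_simulated_gait(self):
        trace, truth = simulate_kinematics(
            TrialPlan(duration=20.0, speed=0.8), fs=100, seed=5)
        sp = instantaneous_speed(trace)
        assert sp.average == pytest.approx(0.8, abs=0.05)

    def test_missing_waist_marker(self):
        trace = _trace_from_z(np.zeros(600), channels=[("L", "foot")])
        with pytest.raises(MissingChannelError):
            instantaneous_speed(trace)

    def test_delta_speed_sign_convention(self):
        a = SpeedSeries(np.array([0.]), np.array([0.6]), 0.6)
        b = SpeedSeries(np.array([0.]), np.array([1.0]), 1.0)
        assert delta_speed(a, b) == pytest.approx(-0.4)
        assert delta_speed(a, a) == 0.0
        mon = SpeedSeries(np.array([0.]), np.array([1.1]), 1.1)
        moff = SpeedSeries(np.array([0.]), np.array([0.8]), 0.8)
        assert delta_speed(mon, moff) == pytest.approx(0.3)


class TestFreezingIndex:
    def test_pure_locomotion_tone(self):
        t = np.arange(0, 12, 0.01)
        ifog = freezing_index(_trace_from_z(np.sin(2 * np.pi * 1.0 * t)))
        assert np.all(ifog.values < 0.05)

    def test_pure_freeze_tone(self):
        t = np.arange(0, 12, 0.01)
        ifog = freezing_index(_trace_from_z(np.sin(2 * np.pi * 5.0 * t)))
        assert np.all(ifog.values > 100)

    def test_mixed_tones_match_direct_fft_oracle(self):
        t = np.arange(0, 12, 0.01)
        z = np.sin(2 * np.pi * 1.0 * t) + np.sin(2 * np.pi * 5.0 * t)
        ifog = freezing_index(_trace_from_z(z))
        assert ifog.values[len(ifog.values) // 2] == pytest.approx(1.0, abs=0.1)
        # independent single-window oracle at the series midpoint
        mid = ifog.times[len(ifog.values) // 2]
        i0 = int((mid - 3.0) * 100)
        oracle = _fft_band_ratio(z[i0:i0 + 600], 100.0)
        assert ifog.values[len(ifog.values) // 2] == pytest.approx(
            oracle, rel=0.1)

    def test_amplitude_invariance(self):
        rng = np.random.default_rng(8)
        z = rng.normal(0, 1, 1500)
        a = freezing_index(_trace_from_z(z))
        b = freezing_index(_trace_from_z(7.3 * z))
        np.testing.assert_allclose(a.values, b.values, rtol=1e-10)

    def test_window_grid(self):
        z = np.random.default_rng(0).normal(0, 1, 1200)
        ifog = freezing_index(_trace_from_z(z))
        assert np.allclose(np.diff(ifog.times), 0.1)
        assert np.all(ifog.values >= 0)

    def test_too_short_trace(self):
        with pytest.raises(InsufficientDataError):
            freezing_index(_trace_from_z(np.zeros(400)))


def _series(values: np.ndarray, start: float = 3.0,
            step: float = 0.1) -> FreezingIndexSeries:
    times = start + step * np.arange(values.size)
    return FreezingIndexSeries(times=times, values=np.asarray(values, float))


class TestSegmentation:
    def test_no_crossing_yields_single_walking_segment(self):
        segs = segment_statuses(_series(np.ones(200)), trial_span=(0.0, 25.9))
        assert len(segs) == 1
        assert segs[0].label == "walking"
        assert (segs[0].start, segs[0].end) == (0.0, 25.9)

    def test_freeze_with_flanks(self):
        # iFOG > 3 exactly over centers [10 s, 13 s] within a 0-20 s trial
        times = 3.0 + 0.1 * np.arange(141)  # 3.0 .. 17.0
        values = np.where((times >= 10.0) & (times <= 13.0), 5.0, 1.0)
        segs = segment_statuses(
            FreezingIndexSeries(times=times, values=values),
            trial_span=(0.0, 20.0))
        got = {(s.label, round(s.start, 6), round(s.end, 6)) for s in segs}
        assert ("freeze", 10.0, 13.0) in got
        assert ("f_pre", 8.5, 10.0) in got
        assert ("f_post", 13.0, 14.5) in got
        walking = sorted((s.start, s.end) for s in segs
                         if s.label == "walking")
        assert walking == [(0.0, 8.5), (14.5, 20.0)]

    def test_close_runs_merge_into_one_freeze(self):
        # two runs separated by a 0.1 s dip: hand run-length enumeration
        # gives intervals [4.0, 5.0] and [5.2, 6.2]; gap 0.2 <= tolerance
        times = 3.0 + 0.1 * np.arange(61)
        values = np.ones(61)
        values[(times >= 4.0) & (times <= 5.0)] = 5.0
        values[(times >= 5.2) & (times <= 6.2)] = 5.0
        segs = segment_statuses(FreezingIndexSeries(times=times, values=values),
                                trial_span=(0.0, 12.0))
        freezes = [(s.start, s.end) for s in segs if s.label == "freeze"]
        assert len(freezes) == 1
        assert freezes[0] == (pytest.approx(4.0), pytest.approx(6.2))

    def test_short_blip_suppressed(self):
        times = 3.0 + 0.1 * np.arange(41)
        values = np.ones(41)
        values[20] = 10.0  # single 0.1 s crossing < 0.5 s minimum
        segs = segment_statuses(FreezingIndexSeries(times=times, values=values),
                                trial_span=(0.0, 10.0))
        assert [s.label for s in segs] == ["walking"]

    def test_partition_property(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            values = np.exp(rng.normal(0.5, 1.5, rng.integers(60, 300)))
            segs = segment_statuses(_series(values))
            segs = sorted(segs, key=lambda s: s.start)
            span = (segs[0].start, segs[-1].end)
            assert span[0] == pytest.approx(0.0)
            for a, b in zip(segs[:-1], segs[1:]):
                assert a.end == pytest.approx(b.start)  # no gaps, no overlap
            assert all(s.duration > 0 for s in segs)

    def test_dual_task_base_label(self):
        segs = segment_statuses(_series(np.ones(100)),
                                base_label="dual_task")
        assert {s.label for s in segs} == {"dual_task"}


class TestFreezeRecovery:
    def test_detected_freezes_overlap_truth(self):
        ious = []
        for seed in range(4):
            plan = TrialPlan(duration=30.0, speed=1.0,
                             freeze_intervals=[(8.0, 13.0), (19.0, 23.5)])
            trace, truth = simulate_kinematics(plan, fs=100, seed=seed)
            ifog = freezing_index(trace)
            segs = segment_statuses(ifog, trial_span=(0.0, 30.0))
            detected = [(s.start, s.end) for s in segs if s.label == "freeze"]
            for ts, te in truth["freeze_intervals"]:
                best = 0.0
                for ds, de in detected:
                    inter = max(0.0, min(te, de) - max(ts, ds))
                    union = max(te, de) - min(ts, ds)
                    best = max(best, inter / union)
                ious.append(best)
        assert np.mean(ious) >= 0.8


class TestStatusSegmentType:
    def test_invalid_label_rejected(self):
        with pytest.raises(InvalidArgumentError):
            StatusSegment("running", 0.0, 1.0)

    def test_reversed_interval_rejected(self):
        with pytest.raises(InvalidArgumentError):
            StatusSegment("walking", 2.0, 1.0)
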