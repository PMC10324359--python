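"""Gait kinematics: walking speed, the freezing index (iFOG), segmentation.

The freezing index quantifies trembling-in-place episodes: within a sliding
window it takes the ratio of kinematic spectral power in the 3-8 Hz "freeze
band" to the 0-3 Hz "locomotion band".  Values above 3 mark freezing; the
1.5 s flanks before/after an episode are labelled ``f_pre``/``f_post`` and
everything else in a gait trial is walking (or dual-task walking).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import InsufficientDataError, InvalidArgumentError, MissingChannelError

__all__ = [
    "MARKER_LOCATIONS",
    "KinematicTrace",
    "SpeedSeries",
    "FreezingIndexSeries",
    "StatusSegment",
    "instantaneous_speed",
    "freezing_index",
    "segment_statuses",
    "delta_speed",
]

MARKER_LOCATIONS = ("foot", "shank", "thigh", "waist")
#: the 8 channels entering the freezing index: 4 locations x 2 sides
IFOG_CHANNELS = tuple((side, loc) for loc in MARKER_LOCATIONS for side in ("L", "R"))

FREEZE_BAND = (3.0, 8.0)
LOCOMOTION_BAND = (0.0, 3.0)


@dataclass
class KinematicTrace:
    """Motion-capture marker trajectories on a shared time base.

    ``markers`` maps (side, location) -> (n_samples, 3) positions in mm
    (x lateral, y forward, z vertical).
    """

    fs: float
    markers: dict[tuple[str, str], np.ndarray]
    trial_id: str = ""
    subject: str = ""
    med_state: str = "Moff"
    dual_task: bool = False

    def __post_init__(self) -> None:
        lengths = {v.shape[0] for v in self.markers.values()}
        if len(lengths) > 1:
            raise InvalidArgumentError("all markers must share one time base")
        for key, v in self.markers.items():
            if not np.all(np.isfinite(v)):
                raise InvalidArgumentError(f"non-finite positions in marker {key}")

    @property
    def n_samples(self) -> int:
        return next(iter(self.markers.values())).shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class SpeedSeries:
    times: np.ndarray            # s
    speed: np.ndarray            # m/s, instantaneous
    average: float               # m/s, arithmetic mean of instantaneous values


@dataclass
class FreezingIndexSeries:
    times: np.ndarray            # window-center times, s
    values: np.ndarray           # dimensionless, >= 0
    window: float = 6.0          # s
    step: float = 0.1            # s
    channels: tuple = IFOG_CHANNELS


@dataclass
class StatusSegment:
    """Labeled half-open time interval [start, end) within a trial."""

    label: str
    start: float
    end: float
    trial_id: str = ""
    subject: str = ""
    med_state: str = "Moff"

    LABELS = ("sitting", "standing", "walking", "dual_task",
              "freeze", "f_pre", "f_post")

    def __post_init__(self) -> None:
        if self.label not in self.LABELS:
            raise InvalidArgumentError(f"unknown status label {self.label!r}")
        if not self.start < self.end:
            raise InvalidArgumentError("segment start must be < end")

    @property
    def duration(self) -> float:
        return self.end - self.start


# --------------------------------------------------------------------------
# Speed
# --------------------------------------------------------------------------

def instantaneous_speed(trace: KinematicTrace) -> SpeedSeries:
    """Instantaneous speed from the waist markers.

    Per sample: Euclidean 3-D displacement to the next sample times the
    sampling rate, converted mm -> m, averaged over left/right waist markers
    when both are present.  The average speed is the arithmetic mean over
    all time points.
    """
    waist = [v for (side, loc), v in trace.markers.items() if loc == "waist"]
    if not waist:
        raise MissingChannelError("no waist marker in trace")
    speeds = []
    for pos in waist:
        step = np.linalg.norm(np.diff(pos, axis=0), axis=1)  # mm per sample
        speeds.append(step * trace.fs / 1000.0)              # m/s
    speed = np.mean(speeds, axis=0)
    times = (np.arange(speed.size) + 0.5) / trace.fs
    return SpeedSeries(times=times, speed=speed, average=float(speed.mean()))


def delta_speed(a: SpeedSeries, b: SpeedSeries) -> float:
    """Difference of average speeds, ``average(a) - average(b)`` (m/s).

    Used for task-induced (dual-task minus walking) and medication-induced
    (Mon minus Moff) speed changes.
    """
    return float(a.average - b.average)


# --------------------------------------------------------------------------
# Freezing index
# --------------------------------------------------------------------------

def _window_band_powers(z: np.ndarray, fs: float, window: float,
                        step: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-window freeze-band and locomotion-band power of one channel.

    Each window is linearly detrended, Hann-tapered and Fourier transformed;
    band power is the sum of squared magnitudes over the band's bins (DC
    excluded from the locomotion band; linear detrending removes it anyway).
    """
    nwin = int(round(window * fs))
    nstep = max(int(round(step * fs)), 1)
    views = sliding_window_view(z, nwin)[::nstep]          # (n_windows, nwin)
    t = np.arange(nwin)
    # linear detrend per window (vectorized least squares on a fixed design)
    tm = t - t.mean()
    denom = float(np.sum(tm ** 2))
    slopes = views @ tm / denom
    detrended = views - views.mean(axis=1, keepdims=True) - np.outer(slopes, tm)
    taper = np.hanning(nwin)
    spec = np.fft.rfft(detrended * taper, axis=1)
    power = np.abs(spec) ** 2
    freqs = np.fft.rfftfreq(nwin, d=1.0 / fs)
    freeze = power[:, (freqs >= FREEZE_BAND[0]) & (freqs <= FREEZE_BAND[1])].sum(axis=1)
    loco = power[:, (freqs > 0) & (freqs < LOCOMOTION_BAND[1])].sum(axis=1)
    centers = (np.arange(views.shape[0]) * nstep + nwin / 2.0) / fs
    return centers, freeze, loco


def freezing_index(trace: KinematicTrace, window: float = 6.0,
                   step: float = 0.1, channel_agg: str = "mean",
                   ) -> FreezingIndexSeries:
    """Freezing index over time: 3-8 Hz power / 0-3 Hz power per window.

    Computed per channel on the vertical (z) component of the eight
    foot/shank/thigh/waist markers present in the trace, then aggregated
    across channels (``channel_agg``: "mean" or "max").  The index is a
    power ratio, hence invariant to amplitude scaling of the trace.
    """
    if trace.duration < window:
        raise InsufficientDataError(
            f"trace duration {trace.duration:.2f} s < window {window} s")
    channels = [key for key in IFOG_CHANNELS if key in trace.markers]
    if not channels:
        raise MissingChannelError("no foot/shank/thigh/waist markers in trace")
    values = []
    centers = None
    for key in channels:
        z = trace.markers[key][:, 2]
        centers, freeze, loco = _window_band_powers(z, trace.fs, window, step)
        values.append(freeze / np.maximum(loco, np.finfo(float).tiny))
    stack = np.vstack(values)
    if channel_agg == "mean":
        agg = stack.mean(axis=0)
    elif channel_agg == "max":
        agg = stack.max(axis=0)
    else:
        raise InvalidArgumentError(f"unknown channel_agg {channel_agg!r}")
    return FreezingIndexSeries(times=centers, values=agg, window=window,
                               step=step, channels=tuple(channels))


# --------------------------------------------------------------------------
# Status segmentation
# --------------------------------------------------------------------------

def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Start/end (inclusive) indices of True runs."""
    if mask.size == 0:
        return []
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return [(int(s), int(e - 1)) for s, e in zip(idx[::2], idx[1::2])]


def segment_statuses(ifog: FreezingIndexSeries, threshold: float = 3.0,
                     flank: float = 1.5, min_freeze: float = 0.5,
                     merge_gap: float = 0.2, trial_span: tuple[float, float] | None = None,
                     base_label: str = "walking", trial_id: str = "",
                     subject: str = "", med_state: str = "Moff",
                     ) -> list[StatusSegment]:
    """Partition a gait trial into freeze / f_pre / f_post / walking segments.

    Maximal runs with iFOG > ``threshold`` become freezes after merging runs
    separated by gaps <= ``merge_gap`` s and dropping runs shorter than
    ``min_freeze`` s.  The ``flank`` s before/after each freeze are labelled
    f_pre/f_post (truncated at trial boundaries; the freeze label wins on
    overlap) and the remainder is ``base_label``.  The output tiles the trial
    span exactly.
    """
    if ifog.values.size == 0:
        raise InsufficientDataError("empty freezing-index series")
    if trial_span is None:
        half = ifog.window / 2.0
        trial_span = (ifog.times[0] - half, ifog.times[-1] + half)
    t0, t1 = trial_span

    above = ifog.values > threshold
    intervals: list[list[float]] = []
    for s, e in _runs(above):
        start, end = float(ifog.times[s]), float(ifog.times[e])
        end = max(end, start + ifog.step)  # single-window run has finite span
        if intervals and start - intervals[-1][1] <= merge_gap + 1e-9:
            intervals[-1][1] = end
        else:
            intervals.append([start, end])
    freezes = [(s, e) for s, e in intervals if e - s >= min_freeze]

    meta = dict(trial_id=trial_id, subject=subject, med_state=med_state)
    freeze_iv = [(max(s, t0), min(e, t1)) for s, e in freezes]
    pre_iv = [(max(s - flank, t0), s) for s, e in freeze_iv]
    post_iv = [(e, min(e + flank, t1)) for s, e in freeze_iv]

    # label elementary intervals by precedence: freeze > f_pre > f_post > base
    bounds = sorted({t0, t1,
                     *(b for iv in freeze_iv + pre_iv + post_iv for b in iv)})
    bounds = [b for b in bounds if t0 <= b <= t1]

    def _label(mid: float) -> str:
        if any(s <= mid < e for s, e in freeze_iv):
            return "freeze"
        if any(s <= mid < e for s, e in pre_iv):
            return "f_pre"
        if any(s <= mid < e for s, e in post_iv):
            return "f_post"
        return base_label

    segments: list[StatusSegment] = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        if e - s <= 0:
            continue
        lab = _label((s + e) / 2.0)
        if segments and segments[-1].label == lab:
            segments[-1].end = e
        else:
            segments.append(StatusSegment(lab, s, e, **meta))
    return segments
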