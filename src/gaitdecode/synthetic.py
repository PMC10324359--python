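"""Synthetic study generator: neural recordings and gait kinematics.

Every downstream stage of the pipeline is testable without patient data
because this module generates recordings with the statistical structure the
analysis assumes, together with full ground truth:

* neural channels = 1/f aperiodic background (frequency-domain shaped white
  noise, exact target power law) + narrowband Gaussian-profile oscillations
  whose log10 peak height depends on motor status, region, walking speed and
  medication state, + 50 Hz line noise + optional broadband movement
  artifacts;
* kinematic marker traces with a 0-3 Hz locomotion band (step oscillation at
  the cadence), 3-8 Hz trembling during freezing-of-gait episodes, and a
  controllable walking speed;
* a cohort layout mirroring a within-subject two-medication-state design
  with five motor statuses.

One master seed spawns per-subject and per-trial child generators through
``numpy.random.SeedSequence(master).spawn`` in a fixed order, so identical
(config, seed) pairs give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidArgumentError
from .kinematics import KinematicTrace, StatusSegment
from .preprocess import NeuralRecording
from .spectral import BANDS

__all__ = [
    "EffectProfile",
    "TrialPlan",
    "CohortConfig",
    "SyntheticTrial",
    "SyntheticStudy",
    "default_effect_profiles",
    "simulate_aperiodic_signal",
    "simulate_status_recording",
    "simulate_kinematics",
    "simulate_cohort",
]

STATUSES = ("sitting", "standing", "walking", "dual_task", "freeze")

#: default contact layout: one 8-contact subdural strip spanning the cortical
#: regions plus a 2-contact segment per STN side
DEFAULT_LAYOUT: dict[str, list[str]] = {
    "ECOG": ["PMC", "PMC", "M1", "M1", "S1", "SPL", "SPL", "SPL"],
    "STNL": ["STN_L", "STN_L"],
    "STNR": ["STN_R", "STN_R"],
}


@dataclass(frozen=True)
class EffectProfile:
    """Oscillation of one (region, band) pair across motor statuses.

    ``amplitudes`` maps status -> log10-power peak height (unitless, >= 0) of
    the band oscillation relative to the aperiodic background.
    ``speed_slope`` shifts the height by (speed - reference_speed) per m/s;
    ``medication_shift`` is added in the Mon state.
    """

    region: str
    band: str
    amplitudes: tuple[tuple[str, float], ...]
    speed_slope: float = 0.0
    reference_speed: float = 0.9
    medication_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.band not in BANDS:
            raise InvalidArgumentError(f"unknown band {self.band!r}")
        for status, amp in self.amplitudes:
            if amp < 0:
                raise InvalidArgumentError("amplitudes must be >= 0")
            if status not in STATUSES:
                raise InvalidArgumentError(f"unknown status {status!r}")

    def height(self, status: str, speed: float | None = None,
               med_state: str = "Moff") -> float:
        amps = dict(self.amplitudes)
        h = amps.get(status, 0.0)
        if speed is not None:
            h += self.speed_slope * (speed - self.reference_speed)
        if med_state == "Mon":
            h += self.medication_shift
        return max(h, 0.0)


def default_effect_profiles() -> list[EffectProfile]:
    """Effect directions the analysis is designed to detect.

    Magnitudes are free parameters of the generator (chosen once as
    realistic log10 peak heights): parietal beta is suppressed by gait and
    carries the dominant status contrast; motor-cortex beta drops from
    sitting to standing and further during freezing and is partially restored
    by medication; premotor alpha rises under dual-task load; subthalamic
    low-frequency power rises during freezing.
    """
    return [
        EffectProfile("SPL", "all_beta",
                      (("sitting", 0.55), ("standing", 0.60), ("walking", 0.10),
                       ("dual_task", 0.32), ("freeze", 0.20))),
        EffectProfile("M1", "all_beta",
                      (("sitting", 0.42), ("standing", 0.32), ("walking", 0.24),
                       ("dual_task", 0.24), ("freeze", 0.15)),
                      medication_shift=0.10),
        EffectProfile("PMC", "alpha",
                      (("sitting", 0.20), ("standing", 0.20), ("walking", 0.26),
                       ("dual_task", 0.38), ("freeze", 0.28))),
        EffectProfile("STN_L", "LFO",
                      (("sitting", 0.20), ("standing", 0.24), ("walking", 0.28),
                       ("dual_task", 0.30), ("freeze", 0.48))),
        EffectProfile("STN_R", "LFO",
                      (("sitting", 0.20), ("standing", 0.24), ("walking", 0.28),
                       ("dual_task", 0.30), ("freeze", 0.48))),
        EffectProfile("SPL", "low_gamma",
                      (("sitting", 0.10), ("standing", 0.10), ("walking", 0.28),
                       ("dual_task", 0.24), ("freeze", 0.26))),
    ]


def _check_profiles(profiles: list[EffectProfile]) -> None:
    seen = set()
    for p in profiles:
        key = (p.region, p.band)
        if key in seen:
            raise InvalidArgumentError(
                f"(region, band) pair {key} appears more than once")
        seen.add(key)


# --------------------------------------------------------------------------
# Spectrally shaped noise
# --------------------------------------------------------------------------

def _shaped_noise(n: int, fs: float, psd: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """White noise shaped in the frequency domain to a target one-sided PSD.

    ``psd`` gives the target density on ``np.fft.rfftfreq(n, 1/fs)``; the DC
    component is zeroed so the output has (exactly) zero mean.
    """
    w = rng.standard_normal(n)
    spec = np.fft.rfft(w)
    spec *= np.sqrt(psd * fs / 2.0)
    spec[0] = 0.0
    return np.fft.irfft(spec, n)


def simulate_aperiodic_signal(duration: float, fs: float, offset: float,
                              exponent: float,
                              seed: int | np.random.Generator = 0) -> np.ndarray:
    """Zero-mean signal whose one-sided PSD follows 10^offset / f^exponent.

    Frequency-domain shaping of white noise (amplitude proportional to
    f^(-exponent/2)) gives exact control of the expected spectrum over the
    whole analysis range.
    """
    if duration <= 0 or fs <= 0:
        raise InvalidArgumentError("duration and fs must be positive")
    if exponent < 0:
        raise InvalidArgumentError("exponent must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration * fs))
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    with np.errstate(divide="ignore"):
        psd = np.where(freqs > 0, 10.0 ** offset / np.where(freqs > 0, freqs, 1.0) ** exponent, 0.0)
    return _shaped_noise(n, fs, psd, rng)


def _narrowband_noise(n: int, fs: float, center: float, sigma: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Gaussian-modulated narrowband noise with unit peak PSD at ``center``."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    psd = np.exp(-((freqs - center) ** 2) / (2.0 * sigma ** 2))
    return _shaped_noise(n, fs, psd, rng)


# --------------------------------------------------------------------------
# Neural recordings
# --------------------------------------------------------------------------

def _segment_gain(n: int, fs: float, segments: list[tuple[float, float, float]],
                  ramp: float = 0.25) -> np.ndarray:
    """Piecewise gain over time with short linear cross-fades at boundaries."""
    gain = np.zeros(n)
    for start, end, g in segments:
        i0, i1 = int(round(start * fs)), min(int(round(end * fs)), n)
        gain[i0:i1] = g
    if ramp > 0 and len(segments) > 1:
        k = max(int(ramp * fs), 1)
        kernel = np.ones(k) / k
        gain = np.convolve(gain, kernel, mode="same")
    return gain


def simulate_status_recording(
    status_schedule: list[StatusSegment],
    profiles: list[EffectProfile] | None = None,
    fs: float = 2000.0,
    layout: dict[str, list[str]] | None = None,
    aperiodic: dict[str, tuple[float, float]] | None = None,
    line_noise_amp: float = 2.0,
    artifact_segments: list[tuple[float, float, float]] | None = None,
    speed: float | None = None,
    med_state: str = "Moff",
    seed: int | np.random.Generator = 0,
    subject: str = "",
    trial_id: str = "",
    intended_status: str = "walking",
) -> tuple[NeuralRecording, dict]:
    """Simulate one trial's multichannel recording from a status schedule.

    Each contact carries an independent realization of its region's aperiodic
    background plus, per status segment, one narrowband oscillation per
    matching (region, band) effect profile whose log10 peak height follows
    the profile.  ``artifact_segments`` are (start, end, power_multiplier)
    intervals receiving a broadband amplitude boost.  Returns the recording
    and a ground-truth dict with per-segment true peak heights.
    """
    if profiles is None:
        profiles = default_effect_profiles()
    _check_profiles(profiles)
    layout = layout or DEFAULT_LAYOUT
    aperiodic = aperiodic or {}
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    t0 = min(s.start for s in status_schedule)
    t1 = max(s.end for s in status_schedule)
    if abs(t0) > 1e-9:
        raise InvalidArgumentError("schedule must start at t=0")
    covered = sum(s.duration for s in status_schedule)
    if abs(covered - t1) > 1e-6:
        raise InvalidArgumentError("schedule must tile the recording")
    n = int(round(t1 * fs))
    times = np.arange(n) / fs

    ch_names: list[str] = []
    regions: list[str] = []
    electrodes: dict[str, list[int]] = {}
    for elec, elec_regions in layout.items():
        rows = []
        for i, region in enumerate(elec_regions, start=1):
            if region not in ("PMC", "M1", "S1", "SPL", "STN_L", "STN_R"):
                raise InvalidArgumentError(f"channel with unknown region {region!r}")
            ch_names.append(f"{elec}{i}")
            regions.append(region)
            rows.append(len(ch_names) - 1)
        electrodes[elec] = rows

    truth: dict = {"segments": [], "med_state": med_state, "speed": speed}
    for seg in status_schedule:
        seg_truth = {"label": seg.label, "start": seg.start, "end": seg.end,
                     "heights": {}}
        for p in profiles:
            seg_truth["heights"][(p.region, p.band)] = p.height(
                seg.label, speed=speed, med_state=med_state)
        truth["segments"].append(seg_truth)

    data = np.empty((len(ch_names), n))
    for ci, region in enumerate(regions):
        b, chi = aperiodic.get(region, (1.0, 1.5) if not region.startswith("STN")
                               else (0.7, 1.5))
        x = simulate_aperiodic_signal(t1, fs, b, chi, rng)
        for p in profiles:
            if p.region != region:
                continue
            band = BANDS[p.band]
            center = (band.low + band.high) / 2.0
            sigma = (band.high - band.low) / 6.0
            # peak PSD needed so the fitted log10 peak height equals h:
            # P_osc(fc) = P_ap(fc) * (10^h - 1)
            p_ap_fc = 10.0 ** b / center ** chi
            gains = []
            for st in truth["segments"]:
                h = st["heights"][(p.region, p.band)]
                gains.append((st["start"], st["end"],
                              np.sqrt(p_ap_fc * (10.0 ** h - 1.0))))
            u = _narrowband_noise(n, fs, center, sigma, rng)
            x = x + u * _segment_gain(n, fs, gains)
        if line_noise_amp > 0:
            x = x + line_noise_amp * np.sin(
                2 * np.pi * 50.0 * times + rng.uniform(0, 2 * np.pi))
        data[ci] = x

    if artifact_segments:
        gain = _segment_gain(n, fs, [(s, e, np.sqrt(m) - 1.0)
                                     for s, e, m in artifact_segments], ramp=0.0)
        data *= 1.0 + gain[None, :]
        truth["artifact_segments"] = list(artifact_segments)

    rec = NeuralRecording(fs=fs, data=data, ch_names=ch_names, regions=regions,
                          electrodes=electrodes, montage="common_average",
                          subject=subject, trial_id=trial_id,
                          med_state=med_state, intended_status=intended_status)
    return rec, truth


# --------------------------------------------------------------------------
# Kinematics
# --------------------------------------------------------------------------

@dataclass
class TrialPlan:
    """Commanded gait-trial plan for the kinematic generator."""

    duration: float                     # s
    speed: float = 0.9                  # m/s commanded during walking
    freeze_intervals: list[tuple[float, float]] = field(default_factory=list)
    dual_task: bool = False
    tremble_freq: float = 5.0           # Hz, inside the 3-8 Hz freeze band
    cadence: float = 1.8                # Hz step oscillation (0.8-2.5)

    def __post_init__(self) -> None:
        iv = sorted(self.freeze_intervals)
        for (s0, e0), (s1, e1) in zip(iv[:-1], iv[1:]):
            if s1 < e0:
                raise InvalidArgumentError("overlapping freeze intervals")
        for s, e in iv:
            if s < 0 or e > self.duration or s >= e:
                raise InvalidArgumentError("freeze interval outside trial")


#: vertical step-oscillation amplitude (mm) and freeze-tremble amplitude (mm)
#: per marker location; tremble/step power ratio ~4 keeps threshold crossings
#: close to the true episode boundaries under the 6 s analysis window
_STEP_AMP = {"foot": 15.0, "shank": 10.0, "thigh": 6.0, "waist": 5.0}
_TREMBLE_AMP = {"foot": 30.0, "shank": 20.0, "thigh": 12.0, "waist": 10.0}


def simulate_kinematics(plan: TrialPlan, fs: float = 100.0,
                        seed: int | np.random.Generator = 0,
                        subject: str = "", trial_id: str = "",
                        med_state: str = "Moff",
                        ) -> tuple[KinematicTrace, dict]:
    """Marker trajectories for one gait trial.

    Walking: forward progress at the commanded speed plus a sinusoidal step
    oscillation at the cadence on the vertical component.  Freezing: forward
    progress stalls and a 3-8 Hz trembling oscillation replaces the step
    oscillation.  Returns the trace and ground truth (true freeze intervals,
    commanded path length, effective average speed).
    """
    if fs not in (100.0, 200.0, 100, 200):
        raise InvalidArgumentError("kinematic fs must be 100 or 200 Hz")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(plan.duration * fs))
    t = np.arange(n) / fs

    walking = np.ones(n, dtype=bool)
    for s, e in plan.freeze_intervals:
        walking[int(round(s * fs)):int(round(e * fs))] = False
    # effective speed: commanded during walking, stalls to zero in freezes
    v = np.where(walking, plan.speed, 0.0)
    # short smoothing so transitions are not step discontinuities
    k = max(int(0.2 * fs), 1)
    v = np.convolve(v, np.ones(k) / k, mode="same")
    forward_mm = np.concatenate(([0.0], np.cumsum(v[:-1]))) / fs * 1000.0

    walk_env = np.convolve(walking.astype(float), np.ones(k) / k, mode="same")
    frz_env = 1.0 - walk_env
    step_osc = np.sin(2 * np.pi * plan.cadence * t)
    tremble_osc = np.sin(2 * np.pi * plan.tremble_freq * t
                         + rng.uniform(0, 2 * np.pi))

    markers: dict[tuple[str, str], np.ndarray] = {}
    for side in ("L", "R"):
        phase = 0.0 if side == "L" else np.pi
        for loc in ("foot", "shank", "thigh", "waist"):
            z = (_STEP_AMP[loc] * walk_env
                 * np.sin(2 * np.pi * plan.cadence * t + phase)
                 + _TREMBLE_AMP[loc] * frz_env * tremble_osc
                 + rng.normal(0.0, 0.5, n))
            x = rng.normal(0.0, 1.0, n).cumsum() * 0.02  # slow lateral drift
            pos = np.column_stack([x, forward_mm, z])
            markers[(side, loc)] = pos

    trace = KinematicTrace(fs=float(fs), markers=markers, trial_id=trial_id,
                           subject=subject, med_state=med_state,
                           dual_task=plan.dual_task)
    truth = {
        "freeze_intervals": list(plan.freeze_intervals),
        "path_length_m": float(v.sum() / fs),
        "average_speed": float(v.mean()),
        "dual_task": plan.dual_task,
    }
    return trace, truth


def sway_trace(duration: float, fs: float = 100.0,
               seed: int | np.random.Generator = 0, **meta) -> KinematicTrace:
    """Low-amplitude 0.2-0.5 Hz postural sway for sitting/standing periods."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration * fs))
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    psd = np.where((freqs >= 0.2) & (freqs <= 0.5), 1.0, 0.0)
    markers = {}
    for side in ("L", "R"):
        for loc in ("foot", "shank", "thigh", "waist"):
            z = 2.0 * _shaped_noise(n, fs, psd, rng) + rng.normal(0, 0.2, n)
            markers[(side, loc)] = np.column_stack(
                [rng.normal(0, 0.2, n), rng.normal(0, 0.2, n), z])
    return KinematicTrace(fs=float(fs), markers=markers, **meta)


# --------------------------------------------------------------------------
# Cohort
# --------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Study-design parameters for the synthetic cohort."""

    n_subjects: int = 6
    med_states: tuple[str, ...] = ("Moff", "Mon")
    trials_per_status: dict = field(default_factory=lambda: {
        "walking": 3, "dual_task": 2, "freezing": 1})
    sit_duration: float = 40.0
    stand_duration: float = 40.0
    gait_duration: float = 24.0
    freeze_trial_duration: float = 30.0
    freeze_intervals: tuple[tuple[float, float], ...] = ((8.0, 13.0), (19.0, 23.5))
    base_speed: float = 0.9             # m/s population mean, walking
    subject_speed_sd: float = 0.08
    trial_speed_sd: float = 0.05
    dual_task_slowdown: float = 0.25    # m/s
    medication_speedup: float = 0.2     # m/s (Mon - Moff)
    speed_beta_coupling: float = -0.3   # m/s change per log10-unit of SPL beta
    beta_trial_sd: float = 0.15         # per-trial SPL-beta height deviation
    profiles: list[EffectProfile] = field(default_factory=default_effect_profiles)
    neural_fs: float = 2000.0
    kin_fs: float = 100.0
    line_noise_amp: float = 2.0
    #: design-only mode: skip signal synthesis (recordings/kinematics are
    #: None) but keep the full trial design and ground truth — used for
    #: cheap parameter-recovery studies on the latent variables
    signals: bool = True

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise InvalidArgumentError("n_subjects must be >= 1")
        _check_profiles(self.profiles)


@dataclass
class SyntheticTrial:
    trial_id: str
    subject: str
    med_state: str
    intended_status: str                # sitting|standing|walking|dual_task|freezing
    recording: NeuralRecording
    kinematics: KinematicTrace
    true_segments: list[StatusSegment]
    true_freeze_intervals: list[tuple[float, float]]
    true_speed: float | None
    true_spl_beta: float | None
    neural_truth: dict


@dataclass
class SyntheticStudy:
    config: CohortConfig
    master_seed: int
    subjects: list[str]
    trials: list[SyntheticTrial]

    def gait_trials(self, med_state: str | None = None) -> list[SyntheticTrial]:
        out = [t for t in self.trials
               if t.intended_status in ("walking", "dual_task", "freezing")]
        if med_state is not None:
            out = [t for t in out if t.med_state == med_state]
        return out


def _spl_profile_with_deviation(profiles: list[EffectProfile],
                                dev: float) -> list[EffectProfile]:
    out = []
    for p in profiles:
        if p.region == "SPL" and "beta" in p.band:
            amps = tuple((s, max(a + dev, 0.0)) for s, a in p.amplitudes)
            out.append(replace(p, amplitudes=amps))
        else:
            out.append(p)
    return out


def simulate_cohort(config: CohortConfig | None = None,
                    seed: int = 0) -> SyntheticStudy:
    """Generate a complete synthetic study.

    Per subject and medication state: one sitting and one standing period and
    the configured numbers of walking, dual-task and freezing gait trials.
    Per gait trial a latent SPL-beta deviation ``d ~ N(0, beta_trial_sd^2)``
    shifts the parietal beta height, and the trial's speed is
    ``subject base + medication effect + speed_beta_coupling * d + noise`` —
    so ground-truth speed and SPL-beta height have the configured linear
    relation with slope ``speed_beta_coupling``.
    """
    config = config or CohortConfig()
    root = np.random.SeedSequence(seed)
    subj_seqs = root.spawn(config.n_subjects)

    subjects = [f"sub{i + 1:02d}" for i in range(config.n_subjects)]
    trials: list[SyntheticTrial] = []
    for si, (subj, seq) in enumerate(zip(subjects, subj_seqs)):
        subj_rng = np.random.default_rng(seq)
        subj_speed = config.base_speed + subj_rng.normal(0, config.subject_speed_sd)
        for med in config.med_states:
            med_speed = subj_speed + (config.medication_speedup
                                      if med == "Mon" else 0.0)
            plans: list[tuple[str, float]] = [
                ("sitting", config.sit_duration),
                ("standing", config.stand_duration),
            ]
            plans += [("walking", config.gait_duration)] \
                * config.trials_per_status.get("walking", 0)
            plans += [("dual_task", config.gait_duration)] \
                * config.trials_per_status.get("dual_task", 0)
            plans += [("freezing", config.freeze_trial_duration)] \
                * config.trials_per_status.get("freezing", 0)

            for ti, (status, duration) in enumerate(plans):
                trial_rng = np.random.default_rng(seq.spawn(1)[0])
                trial_id = f"{subj}_{med}_t{ti:02d}_{status}"
                meta = dict(subject=subj, trial_id=trial_id, med_state=med)

                if status in ("sitting", "standing"):
                    segs = [StatusSegment(status, 0.0, duration, **meta)]
                    if config.signals:
                        rec, truth = simulate_status_recording(
                            segs, config.profiles, fs=config.neural_fs,
                            line_noise_amp=config.line_noise_amp, med_state=med,
                            seed=trial_rng, intended_status=status,
                            subject=subj, trial_id=trial_id)
                        kin = sway_trace(duration, config.kin_fs, trial_rng,
                                         **meta)
                    else:
                        rec, kin, truth = None, None, {}
                    trials.append(SyntheticTrial(
                        trial_id, subj, med, status, rec, kin, segs, [],
                        None, None, truth))
                    continue

                base = "dual_task" if status == "dual_task" else "walking"
                dev = trial_rng.normal(0, config.beta_trial_sd)
                spl = next((p for p in config.profiles
                            if p.region == "SPL" and "beta" in p.band), None)
                if spl is not None:
                    # couple speed to the realized (non-negative) beta height
                    # so ground truth follows the configured linear relation
                    h_base = spl.height(base)
                    dev = max(h_base + dev, 0.0) - h_base
                speed = (med_speed
                         + config.speed_beta_coupling * dev
                         + trial_rng.normal(0, config.trial_speed_sd))
                speed = max(speed, 0.2)
                if status == "dual_task":
                    speed = max(speed - config.dual_task_slowdown, 0.2)
                freeze_iv = (list(config.freeze_intervals)
                             if status == "freezing" else [])
                plan = TrialPlan(duration=duration, speed=speed,
                                 freeze_intervals=freeze_iv,
                                 dual_task=(status == "dual_task"))
                if config.signals:
                    kin, kin_truth = simulate_kinematics(
                        plan, config.kin_fs, trial_rng, **meta)
                else:
                    kin = None

                segs: list[StatusSegment] = []
                cursor = 0.0
                for s, e in sorted(freeze_iv):
                    if s > cursor:
                        segs.append(StatusSegment(base, cursor, s, **meta))
                    segs.append(StatusSegment("freeze", s, e, **meta))
                    cursor = e
                if cursor < duration:
                    segs.append(StatusSegment(base, cursor, duration, **meta))

                profiles = _spl_profile_with_deviation(config.profiles, dev)
                if config.signals:
                    rec, truth = simulate_status_recording(
                        segs, profiles, fs=config.neural_fs,
                        line_noise_amp=config.line_noise_amp, speed=speed,
                        med_state=med, seed=trial_rng, intended_status=status,
                        subject=subj, trial_id=trial_id)
                else:
                    rec, truth = None, {}
                spl_beta = next(
                    (p.height(base, speed=speed, med_state=med)
                     for p in profiles
                     if p.region == "SPL" and "beta" in p.band),
                    None)
                trials.append(SyntheticTrial(
                    trial_id, subj, med, status, rec, kin, segs,
                    freeze_iv, speed, spl_beta, truth))
    return SyntheticStudy(config=config, master_seed=seed,
                          subjects=subjects, trials=trials)
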