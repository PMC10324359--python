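"""Conditioning of intracranial recordings and status-labelled epoching.

Recordings arrive common-average referenced at 2000 Hz.  The pipeline notches
50 Hz line noise and its harmonics, band-passes 2-200 Hz (all zero-phase),
re-references to a bipolar montage between adjacent contacts for spatial
specificity, cuts non-overlapping 2 s epochs inside each labelled status
segment, and rejects trials with gross amplitude or drift artifacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _sig

from .errors import InvalidArgumentError
from .kinematics import StatusSegment

__all__ = [
    "REGIONS",
    "FEATURE_REGIONS",
    "NeuralRecording",
    "Epoch",
    "notch_and_bandpass",
    "bipolar_montage",
    "epoch_by_status",
    "reject_artifact_trials",
]

#: all recognised region tags
REGIONS = ("PMC", "M1", "S1", "SPL", "STN_L", "STN_R")
#: regions entering the feature set (S1 carried through but excluded; the
#: two STN sides are pooled into one "STN" region downstream)
FEATURE_REGIONS = ("PMC", "M1", "SPL", "STN")

EPOCH_LABELS = ("sitting", "standing", "walking", "dual_task", "freeze")


@dataclass
class NeuralRecording:
    """Multichannel neural time series (uV) with channel/region metadata.

    ``electrodes`` groups channel indices by physical electrode in contact
    order; the bipolar montage differences adjacent contacts within each
    group.
    """

    fs: float
    data: np.ndarray                 # (n_channels, n_samples), uV
    ch_names: list[str]
    regions: list[str]
    electrodes: dict[str, list[int]] = field(default_factory=dict)
    montage: str = "common_average"
    subject: str = ""
    trial_id: str = ""
    med_state: str = "Moff"
    intended_status: str = "walking"

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if len(self.ch_names) != self.data.shape[0]:
            raise InvalidArgumentError("ch_names length != number of channels")
        if len(self.regions) != self.data.shape[0]:
            raise InvalidArgumentError("regions length != number of channels")
        for r in self.regions:
            if r not in REGIONS + ("other", "boundary"):
                raise InvalidArgumentError(f"unknown region tag {r!r}")
        if not self.electrodes:
            self.electrodes = {"E0": list(range(self.data.shape[0]))}

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class Epoch:
    """A 2 s status-labelled slice of a preprocessed recording."""

    data: np.ndarray                 # (n_channels, length*fs)
    fs: float
    label: str
    ch_names: list[str]
    regions: list[str]
    subject: str = ""
    trial_id: str = ""
    med_state: str = "Moff"
    window_index: int = 0
    start: float = 0.0

    def __post_init__(self) -> None:
        if self.label not in EPOCH_LABELS:
            raise InvalidArgumentError(f"epoch label {self.label!r} not a class")


# --------------------------------------------------------------------------
# Filtering
# --------------------------------------------------------------------------

def notch_and_bandpass(rec: NeuralRecording, line: float = 50.0,
                       band: tuple[float, float] = (2.0, 200.0),
                       notch_width: float = 4.0) -> NeuralRecording:
    """Zero-phase 4th-order Butterworth band-pass plus band-stop notches.

    Notches are ``notch_width``-Hz-wide stop bands at the line frequency and
    every harmonic inside the pass band ({50, 100, 150} Hz by default).
    Forward-backward filtering gives zero group delay.
    """
    lo, hi = band
    if rec.fs <= 2 * hi:
        raise InvalidArgumentError(
            f"fs {rec.fs} too low for band upper edge {hi} Hz")
    out = rec.data.copy()
    sos_bp = _sig.butter(4, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    out = _sig.sosfiltfilt(sos_bp, out, axis=1)
    h = line
    while h < hi:
        sos_bs = _sig.butter(4, [h - notch_width / 2, h + notch_width / 2],
                             btype="bandstop", fs=rec.fs, output="sos")
        out = _sig.sosfiltfilt(sos_bs, out, axis=1)
        h += line
    return replace(rec, data=out)


def filter_power_response(freqs: np.ndarray, fs: float, line: float = 50.0,
                          band: tuple[float, float] = (2.0, 200.0),
                          notch_width: float = 4.0) -> np.ndarray:
    """Power transfer of the zero-phase filter cascade at ``freqs``.

    Forward-backward filtering applies |H(f)|^2 in amplitude, so the PSD is
    scaled by |H(f)|^4.  Dividing an estimated PSD by this response undoes
    the filter skirts (e.g. the roll-off below the 200 Hz edge) before
    spectral parameterization.
    """
    lo, hi = band
    soses = [_sig.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")]
    h = line
    while h < hi:
        soses.append(_sig.butter(4, [h - notch_width / 2, h + notch_width / 2],
                                 btype="bandstop", fs=fs, output="sos"))
        h += line
    gain = np.ones_like(freqs, dtype=float)
    for sos in soses:
        _, resp = _sig.sosfreqz(sos, worN=2 * np.pi * freqs / fs)
        gain *= np.abs(resp) ** 2
    return gain ** 2


# --------------------------------------------------------------------------
# Bipolar montage
# --------------------------------------------------------------------------

def bipolar_montage(rec: NeuralRecording) -> NeuralRecording:
    """Difference adjacent contacts within each electrode.

    Output channel i = contact i - contact i+1; per electrode with n
    contacts, n-1 bipolar channels.  The region tag is kept only when both
    contacts share a region, otherwise ``boundary``.  Single-contact
    electrodes are skipped with a warning.  Any component common to all
    contacts of an electrode (e.g. the common-average reference) is removed
    exactly.
    """
    data_rows, names, regions = [], [], []
    electrodes: dict[str, list[int]] = {}
    for elec, idx in rec.electrodes.items():
        if len(idx) < 2:
            warnings.warn(f"electrode {elec} has a single contact; skipped",
                          stacklevel=2)
            continue
        rows = []
        for a, b in zip(idx[:-1], idx[1:]):
            data_rows.append(rec.data[a] - rec.data[b])
            names.append(f"{rec.ch_names[a]}-{rec.ch_names[b]}")
            ra, rb = rec.regions[a], rec.regions[b]
            regions.append(ra if ra == rb else "boundary")
            rows.append(len(data_rows) - 1)
        electrodes[elec] = rows
    if not data_rows:
        raise InvalidArgumentError("no electrode with >= 2 contacts")
    return replace(rec, data=np.vstack(data_rows), ch_names=names,
                   regions=regions, electrodes=electrodes, montage="bipolar")


# --------------------------------------------------------------------------
# Epoching
# --------------------------------------------------------------------------

def epoch_by_status(rec: NeuralRecording, segments: list[StatusSegment],
                    length: float = 2.0) -> list[Epoch]:
    """Cut non-overlapping ``length``-s windows inside each status segment.

    Windows are aligned to the segment onset; partial windows are discarded
    and f_pre/f_post segments contribute no epochs.
    """
    n_len = int(round(length * rec.fs))
    epochs: list[Epoch] = []
    for seg in segments:
        if seg.label not in EPOCH_LABELS:
            continue
        n_win = int(np.floor((seg.end - seg.start) / length + 1e-9))
        for k in range(n_win):
            start = seg.start + k * length
            i0 = int(round(start * rec.fs))
            if i0 + n_len > rec.n_samples:
                break
            epochs.append(Epoch(
                data=rec.data[:, i0:i0 + n_len], fs=rec.fs, label=seg.label,
                ch_names=rec.ch_names, regions=rec.regions,
                subject=rec.subject or seg.subject,
                trial_id=rec.trial_id or seg.trial_id,
                med_state=rec.med_state, window_index=k, start=start))
    return epochs


# --------------------------------------------------------------------------
# Artifact / drift rejection
# --------------------------------------------------------------------------

def _drift_power(rec: NeuralRecording, hi: float = 1.0) -> float:
    """Mean 0-``hi`` Hz power across channels (Welch, long segments)."""
    nper = min(rec.n_samples, int(4 * rec.fs))
    freqs, psd = _sig.welch(rec.data, fs=rec.fs, nperseg=nper, axis=1)
    band = freqs <= hi
    return float(psd[:, band].sum(axis=1).mean())


def reject_artifact_trials(trials: list[NeuralRecording], amp_k: float = 8.0,
                           drift_k: float = 10.0, amp_floor: float = 1e-6,
                           ) -> tuple[list[NeuralRecording], list[dict]]:
    """Automated surrogate for manual artifact/drift screening of trials.

    A trial is rejected when its peak absolute amplitude exceeds the session
    median + ``amp_k`` x MAD (MAD floored at ``amp_floor`` uV so identical
    trials are never rejected), or when its 0-1 Hz drift power exceeds
    ``drift_k`` x the session median.  Returns the kept trials and a log with
    one entry per trial recording which rule (if any) fired.
    """
    if not trials:
        return [], []
    peaks = np.array([float(np.abs(t.data).max()) for t in trials])
    med = np.median(peaks)
    mad = max(float(np.median(np.abs(peaks - med))), amp_floor)
    amp_thresh = med + amp_k * mad

    drifts = np.array([_drift_power(t) for t in trials])
    drift_thresh = drift_k * max(float(np.median(drifts)), np.finfo(float).tiny)

    kept, log = [], []
    for t, peak, drift in zip(trials, peaks, drifts):
        entry = {"trial_id": t.trial_id, "subject": t.subject,
                 "peak_uv": float(peak), "drift_power": float(drift),
                 "rule": None}
        if peak > amp_thresh:
            entry["rule"] = "amplitude"
        elif drift > drift_thresh:
            entry["rule"] = "drift"
        else:
            kept.append(t)
        log.append(entry)
    return kept, log
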