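"""On-disk formats: recordings (CSV + JSON sidecar or EDF), kinematics CSV,
segment/speed/feature tables (TSV) and the study manifest.

A recording is stored as a samples CSV (one column per channel, uV) next to
a JSON sidecar carrying the sampling rate, channel names, region tags,
electrode grouping and trial metadata.  EDF files are read through MNE when
it is installed.  Kinematics use a long-format CSV with columns
``time_s, marker_id, side, x_mm, y_mm, z_mm``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, InvalidArgumentError
from .kinematics import KinematicTrace, StatusSegment
from .preprocess import REGIONS, NeuralRecording

__all__ = [
    "StudyManifest",
    "ManifestEntry",
    "write_recording",
    "read_recording",
    "write_kinematics",
    "read_kinematics",
    "write_segments",
    "read_segments",
]


# --------------------------------------------------------------------------
# Neural recordings
# --------------------------------------------------------------------------

def write_recording(rec: NeuralRecording, path) -> None:
    """Write samples to ``<path>.csv`` and metadata to ``<path>.json``."""
    path = Path(path)
    df = pd.DataFrame(rec.data.T, columns=rec.ch_names)
    df.to_csv(path.with_suffix(".csv"), index=False, float_format="%.4f")
    sidecar = {
        "fs": rec.fs,
        "ch_names": rec.ch_names,
        "regions": rec.regions,
        "electrodes": rec.electrodes,
        "montage": rec.montage,
        "subject": rec.subject,
        "trial_id": rec.trial_id,
        "med_state": rec.med_state,
        "intended_status": rec.intended_status,
        "units": "uV",
    }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def _read_recording_csv(path: Path, expected_fs: float | None) -> NeuralRecording:
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FormatError(f"missing JSON sidecar for {path}")
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    if expected_fs is not None and meta.get("fs") != expected_fs:
        raise FormatError(
            f"{path}: sidecar fs {meta.get('fs')} != declared fs {expected_fs}")
    try:
        df = pd.read_csv(path.with_suffix(".csv"))
    except Exception as exc:  # noqa: BLE001 - surface parser position
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    ch_names = meta.get("ch_names", list(df.columns))
    regions = meta.get("regions")
    if regions is None:
        warnings.warn(f"{path}: sidecar has no region map; tagging channels "
                      "'other'", stacklevel=2)
        regions = ["other"] * len(ch_names)
    regions = [r if r in REGIONS + ("other", "boundary") else _warn_region(r)
               for r in regions]
    electrodes = {k: list(v) for k, v in meta.get("electrodes", {}).items()}
    return NeuralRecording(
        fs=float(meta["fs"]), data=df[ch_names].to_numpy().T,
        ch_names=list(ch_names), regions=regions, electrodes=electrodes,
        montage=meta.get("montage", "common_average"),
        subject=meta.get("subject", ""), trial_id=meta.get("trial_id", ""),
        med_state=meta.get("med_state", "Moff"),
        intended_status=meta.get("intended_status", "walking"))


def _warn_region(tag: str) -> str:
    warnings.warn(f"unknown region tag {tag!r}; using 'other'", stacklevel=3)
    return "other"


def _read_recording_edf(path: Path) -> NeuralRecording:
    try:
        import mne
    except ImportError as exc:
        raise FormatError("EDF support requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # V -> uV
    return NeuralRecording(fs=float(raw.info["sfreq"]), data=data,
                           ch_names=list(raw.ch_names),
                           regions=["other"] * len(raw.ch_names))


def read_recording(path, expected_fs: float | None = None) -> NeuralRecording:
    """Read a recording from CSV+JSON (or EDF if the path ends in .edf)."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return _read_recording_edf(path)
    return _read_recording_csv(path, expected_fs)


# --------------------------------------------------------------------------
# Kinematics
# --------------------------------------------------------------------------

def write_kinematics(trace: KinematicTrace, path) -> None:
    frames = []
    for (side, loc), pos in trace.markers.items():
        t = np.arange(pos.shape[0]) / trace.fs
        frames.append(pd.DataFrame({
            "time_s": t, "marker_id": loc, "side": side,
            "x_mm": pos[:, 0], "y_mm": pos[:, 1], "z_mm": pos[:, 2]}))
    pd.concat(frames).to_csv(path, index=False, float_format="%.3f")


def read_kinematics(path, fs: float | None = None, **meta) -> KinematicTrace:
    df = pd.read_csv(path)
    required = {"time_s", "marker_id", "side", "x_mm", "y_mm", "z_mm"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: missing columns {required - set(df.columns)}")
    markers = {}
    for (side, loc), grp in df.groupby(["side", "marker_id"], sort=True):
        grp = grp.sort_values("time_s")
        markers[(side, loc)] = grp[["x_mm", "y_mm", "z_mm"]].to_numpy()
        if fs is None:
            dt = np.diff(grp["time_s"].to_numpy())
            fs = 1.0 / float(np.median(dt))
    return KinematicTrace(fs=float(round(fs)), markers=markers, **meta)


# --------------------------------------------------------------------------
# Segments / tables
# --------------------------------------------------------------------------

def write_segments(segments: list[StatusSegment], path) -> None:
    pd.DataFrame([{
        "trial_id": s.trial_id, "subject": s.subject, "med_state": s.med_state,
        "label": s.label, "start_s": s.start, "end_s": s.end,
    } for s in segments]).to_csv(path, sep="\t", index=False)


def read_segments(path) -> list[StatusSegment]:
    df = pd.read_csv(path, sep="\t")
    return [StatusSegment(r.label, float(r.start_s), float(r.end_s),
                          trial_id=str(r.trial_id), subject=str(r.subject),
                          med_state=str(r.med_state))
            for r in df.itertuples()]


# --------------------------------------------------------------------------
# Manifest
# --------------------------------------------------------------------------

@dataclass
class ManifestEntry:
    trial_id: str
    subject: str
    med_state: str
    intended_status: str
    recording_path: str
    kinematics_path: str | None = None


@dataclass
class StudyManifest:
    """Per-trial file listing for a study directory."""

    root: Path
    entries: list[ManifestEntry] = field(default_factory=list)

    @classmethod
    def load(cls, path) -> "StudyManifest":
        path = Path(path)
        df = pd.read_csv(path, sep="\t")
        entries = []
        seen: dict[str, set] = {}
        for r in df.itertuples():
            kin = None if pd.isna(getattr(r, "kinematics_path", np.nan)) \
                else str(r.kinematics_path)
            e = ManifestEntry(str(r.trial_id), str(r.subject), str(r.med_state),
                              str(r.intended_status), str(r.recording_path), kin)
            if e.trial_id in seen.setdefault(e.subject, set()):
                raise InvalidArgumentError(
                    f"duplicate trial id {e.trial_id} for {e.subject}")
            seen[e.subject].add(e.trial_id)
            rec = path.parent / e.recording_path
            if not rec.with_suffix(".csv").exists() and not rec.exists():
                raise FormatError(f"manifest references missing file {rec}")
            entries.append(e)
        return cls(root=path.parent, entries=entries)

    def save(self, path) -> None:
        pd.DataFrame([e.__dict__ for e in self.entries]).to_csv(
            path, sep="\t", index=False)
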