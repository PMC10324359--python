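"""End-to-end pipeline: segmentation -> preprocessing -> spectral features ->
classification -> statistics, with per-stage accounting and provenance.

The pipeline consumes either an in-memory synthetic study or a manifest of
on-disk recordings, and writes all stage outputs (segments TSV, feature TSV,
classification JSON, stats TSV, provenance JSON) into a results directory.
Every rejected trial is logged with the rule that fired.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .decode import build_feature_table, nested_cv_classify
from .io import StudyManifest, read_kinematics, read_recording, write_segments
from .kinematics import (StatusSegment, freezing_index, instantaneous_speed,
                         segment_statuses)
from .preprocess import (NeuralRecording, bipolar_montage, epoch_by_status,
                         filter_power_response, notch_and_bandpass,
                         reject_artifact_trials)
from .spectral import fit_spectral_model, flag_gait_artifact, welch_psd
from .stats import friedman_conover, lmm_speed_beta
from .synthetic import SyntheticStudy

__all__ = ["run_pipeline", "PipelineResult"]

GAIT_STATUSES = ("walking", "dual_task", "freezing")


class _Trial:
    """Uniform in-memory view of one trial."""

    def __init__(self, trial_id, subject, med_state, intended_status,
                 recording, kinematics):
        self.trial_id = trial_id
        self.subject = subject
        self.med_state = med_state
        self.intended_status = intended_status
        self.recording = recording
        self.kinematics = kinematics


def _load_trials(source) -> list[_Trial]:
    if isinstance(source, SyntheticStudy):
        return [_Trial(t.trial_id, t.subject, t.med_state, t.intended_status,
                       t.recording, t.kinematics) for t in source.trials]
    if isinstance(source, StudyManifest):
        trials = []
        for e in source.entries:
            rec = read_recording(source.root / e.recording_path)
            rec.subject, rec.trial_id = e.subject, e.trial_id
            rec.med_state, rec.intended_status = e.med_state, e.intended_status
            kin = None
            if e.kinematics_path:
                kin = read_kinematics(source.root / e.kinematics_path,
                                      subject=e.subject, trial_id=e.trial_id,
                                      med_state=e.med_state,
                                      dual_task=e.intended_status == "dual_task")
            trials.append(_Trial(e.trial_id, e.subject, e.med_state,
                                 e.intended_status, rec, kin))
        return trials
    raise TypeError(f"unsupported pipeline source: {type(source)!r}")


def _trial_spectrum_model(rec: NeuralRecording, cfg: PipelineConfig):
    """Channel-averaged PSD of a whole trial, parameterized (with the known
    filter response divided out)."""
    psds = [welch_psd(rec.data[ch], rec.fs, cfg.n_fft, cfg.n_overlap)
            for ch in range(rec.data.shape[0])]
    mean_psd = psds[0]
    mean_psd.psd = np.mean([s.psd for s in psds], axis=0)
    correction = np.maximum(filter_power_response(
        mean_psd.freqs, rec.fs, cfg.line_freq, cfg.band), 1e-8)
    mean_psd.psd = mean_psd.psd / correction
    return fit_spectral_model(mean_psd, fit_range=cfg.fit_range,
                              max_n_peaks=cfg.max_n_peaks,
                              peak_threshold=cfg.peak_threshold)


def run_pipeline(source, config: PipelineConfig | None = None,
                 out_dir=None, seed: int = 0) -> dict:
    """Run the full analysis and return (and optionally write) its results.

    Stages, in order: kinematic segmentation of gait trials; zero-phase
    filtering and bipolar re-referencing; amplitude/drift trial rejection;
    the 1/f gait-artifact rule against the session's resting spectra;
    status-labelled 2 s epoching; periodic band-power feature extraction;
    nested cross-validated classification per medication state; freezing
    index / speed statistics and the speed-beta mixed model.
    """
    cfg = config or PipelineConfig()
    trials = _load_trials(source)
    counts = {"trials_in": len(trials)}

    # ---- stage 1: kinematic segmentation + speed --------------------------
    all_segments: list[StatusSegment] = []
    speed_rows = []
    trial_segments: dict[str, list[StatusSegment]] = {}
    for t in trials:
        meta = dict(trial_id=t.trial_id, subject=t.subject,
                    med_state=t.med_state)
        if t.intended_status in GAIT_STATUSES:
            base = ("dual_task" if t.intended_status == "dual_task"
                    else "walking")
            ifog = freezing_index(t.kinematics, cfg.ifog_window, cfg.ifog_step,
                                  cfg.channel_agg)
            segs = segment_statuses(
                ifog, cfg.freeze_threshold, cfg.flank, cfg.min_freeze,
                cfg.merge_gap, trial_span=(0.0, t.kinematics.duration),
                base_label=base, **meta)
            sp = instantaneous_speed(t.kinematics)
            speed_rows.append({**meta, "intended_status": t.intended_status,
                               "average_speed": sp.average,
                               "mean_ifog": float(ifog.values.mean())})
        else:
            segs = [StatusSegment(t.intended_status, 0.0,
                                  t.recording.duration, **meta)]
        trial_segments[t.trial_id] = segs
        all_segments.extend(segs)
    speed_table = pd.DataFrame(speed_rows)

    # ---- stage 2: filtering + montage -------------------------------------
    for t in trials:
        rec = notch_and_bandpass(t.recording, cfg.line_freq, cfg.band)
        if cfg.bipolar:
            rec = bipolar_montage(rec)
        t.recording = rec

    # ---- stage 3: amplitude/drift rejection -------------------------------
    kept_recs, reject_log = reject_artifact_trials(
        [t.recording for t in trials], cfg.amp_k, cfg.drift_k)
    kept_ids = {r.trial_id for r in kept_recs}
    trials = [t for t in trials if t.trial_id in kept_ids]
    counts["trials_after_amplitude_drift"] = len(trials)

    # ---- stage 4: 1/f gait-artifact rule ----------------------------------
    gait_log = []
    for (subject, med), group in _groupby(trials, lambda t: (t.subject,
                                                             t.med_state)):
        rest = [t for t in group
                if t.intended_status in ("sitting", "standing")]
        gait = [t for t in group if t.intended_status in GAIT_STATUSES]
        if not rest or not gait:
            continue
        rest_model = _session_rest_model(rest, cfg)
        for t in gait:
            walk_model = _trial_spectrum_model(t.recording, cfg)
            flagged, ratio = flag_gait_artifact(walk_model, rest_model,
                                                cfg.artifact_threshold)
            gait_log.append({"trial_id": t.trial_id, "subject": subject,
                             "med_state": med, "aperiodic_ratio": ratio,
                             "flagged": flagged})
            if flagged:
                t.flagged = True
    flagged_ids = {g["trial_id"] for g in gait_log if g["flagged"]}
    trials = [t for t in trials if t.trial_id not in flagged_ids]
    counts["trials_after_gait_artifact"] = len(trials)
    if not trials:
        raise RuntimeError("stage gait_artifact: all trials rejected")

    # ---- stage 5: epoching + features -------------------------------------
    epochs = []
    for t in trials:
        epochs.extend(epoch_by_status(t.recording,
                                      trial_segments[t.trial_id],
                                      cfg.epoch_length))
    counts["epochs"] = len(epochs)
    features = build_feature_table(epochs, cfg.fit_range, cfg.n_fft,
                                   cfg.n_overlap, compensate_band=cfg.band)
    counts["epochs_per_class"] = features["label"].value_counts().to_dict()

    # ---- stage 6: classification per medication state ---------------------
    classification = {}
    for med in sorted(features["med_state"].unique()):
        sub = features[features["med_state"] == med]
        present = sub["label"].value_counts()
        usable = present[present >= cfg.outer_k].index
        if len(usable) < 2:
            warnings.warn(f"{med}: fewer than two usable classes; "
                          "classification skipped", stacklevel=2)
            continue
        sub = sub[sub["label"].isin(usable)]
        classification[med] = nested_cv_classify(
            sub, n_search=cfg.n_search, outer_k=cfg.outer_k,
            inner_k=cfg.inner_k, seed=seed)

    # ---- stage 7: statistics ----------------------------------------------
    stats_out = _gait_statistics(speed_table, features, cfg)

    results = {"counts": counts, "segments": all_segments,
               "speed_table": speed_table, "features": features,
               "classification": classification, "stats": stats_out,
               "reject_log": reject_log, "gait_artifact_log": gait_log}

    if out_dir is not None:
        _write_results(results, cfg, out_dir, seed)
    return results


def _groupby(items, key):
    groups: dict = {}
    for it in items:
        groups.setdefault(key(it), []).append(it)
    return groups.items()


def _session_rest_model(rest_trials, cfg: PipelineConfig):
    """Average sitting+standing PSD of a session, parameterized."""
    psds = []
    fs = rest_trials[0].recording.fs
    for t in rest_trials:
        for ch in range(t.recording.data.shape[0]):
            psds.append(welch_psd(t.recording.data[ch], t.recording.fs,
                                  cfg.n_fft, cfg.n_overlap))
    mean = psds[0]
    mean.psd = np.mean([s.psd for s in psds], axis=0)
    correction = np.maximum(filter_power_response(
        mean.freqs, fs, cfg.line_freq, cfg.band), 1e-8)
    mean.psd = mean.psd / correction
    return fit_spectral_model(mean, fit_range=cfg.fit_range,
                              max_n_peaks=cfg.max_n_peaks,
                              peak_threshold=cfg.peak_threshold)


def _gait_statistics(speed_table: pd.DataFrame, features: pd.DataFrame,
                     cfg: PipelineConfig) -> dict:
    out: dict = {}
    if speed_table.empty:
        return out
    # Friedman across walking / dual-task / freezing on per-subject means
    piv_if = speed_table.pivot_table(index="subject",
                                     columns="intended_status",
                                     values="mean_ifog")
    piv_sp = speed_table.pivot_table(index="subject",
                                     columns="intended_status",
                                     values="average_speed")
    for name, piv in (("ifog", piv_if), ("speed", piv_sp)):
        piv = piv.dropna()
        if piv.shape[0] >= 5 and piv.shape[1] >= 3:
            omni, pairs = friedman_conover(piv.to_numpy(),
                                           list(piv.columns))
            out[f"friedman_{name}"] = {
                "omnibus": omni.__dict__,
                "pairwise": [p.__dict__ for p in pairs]}

    # speed ~ SPL beta mixed model on per-trial rows
    beta = (features[features["label"].isin(("walking", "dual_task"))]
            .groupby(["subject", "med_state", "trial_id"])["SPL_all_beta"]
            .mean().reset_index())
    merged = speed_table.merge(beta, on=["subject", "med_state", "trial_id"])
    merged = merged.dropna(subset=["SPL_all_beta"])
    if (merged.groupby("subject").size() >= 2).sum() >= 3:
        try:
            fit = lmm_speed_beta(merged, speed_col="average_speed",
                                 beta_col="SPL_all_beta")
            out["lmm_speed_beta"] = {
                "coef": fit.coef, "se": fit.se, "p": fit.p,
                "conf_int": {k: list(v) for k, v in fit.conf_int.items()},
                "n_obs": fit.n_obs, "n_subjects": fit.n_subjects,
                "singular": fit.singular}
        except Exception as exc:  # noqa: BLE001 - stats are best-effort here
            out["lmm_speed_beta"] = {"error": str(exc)}
    return out


def _write_results(results: dict, cfg: PipelineConfig, out_dir,
                   seed: int) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_segments(results["segments"], out / "segments.tsv")
    results["speed_table"].to_csv(out / "speed.tsv", sep="\t", index=False)
    results["features"].to_csv(out / "features.tsv", sep="\t", index=False)
    for med, res in results["classification"].items():
        res.to_json(out / f"classification_{med}.json")
    with open(out / "stats.json", "w") as fh:
        json.dump(results["stats"], fh, indent=1, default=_jsonable)
    provenance = {
        "version": __version__,
        "seed": seed,
        "config": asdict(cfg),
        "counts": results["counts"],
        "rejected_trials": [e for e in results["reject_log"]
                            if e["rule"] is not None],
        "gait_artifact_flags": [g for g in results["gait_artifact_log"]
                                if g["flagged"]],
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=1, sort_keys=True, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)
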