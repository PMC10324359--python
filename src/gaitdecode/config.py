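"""Pipeline configuration: every tunable in one place.

Defaults reproduce the analysis parameters the method was designed with:
6 s / 0.1 s freezing-index window and step, freeze threshold 3 with 1.5 s
flanks, 2-200 Hz band, 50 Hz line frequency, Welch n_fft 2000 / n_overlap
1000, 2 s epochs, nested 5-fold cross-validation with 25 search rounds, and
a Bonferroni family of 8 (the bands within a region).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # kinematics / freezing index
    ifog_window: float = 6.0            # s
    ifog_step: float = 0.1              # s
    freeze_threshold: float = 3.0
    flank: float = 1.5                  # s, f_pre / f_post
    min_freeze: float = 0.5             # s, minimum episode duration
    merge_gap: float = 0.2              # s, gap-merge tolerance
    channel_agg: str = "mean"           # "mean" or "max" across iFOG channels
    speed_lowpass: float | None = None  # optional Hz low-pass before speed

    # preprocessing
    line_freq: float = 50.0             # Hz
    band: tuple[float, float] = (2.0, 200.0)
    bipolar: bool = True
    amp_k: float = 8.0                  # robust amplitude-rejection multiplier
    drift_k: float = 10.0               # drift-rejection multiplier

    # epoching / spectra
    epoch_length: float = 2.0           # s
    n_fft: int = 2000
    n_overlap: int = 1000
    fit_range: tuple[float, float] = (2.0, 200.0)
    max_n_peaks: int = 6
    peak_threshold: float = 0.1         # log10-units
    artifact_threshold: float = 0.5     # 1/f gait-artifact rule (50%)

    # classification
    outer_k: int = 5
    inner_k: int = 5
    n_search: int = 25
    seed: int = 0

    # statistics
    family_size: int = 8
    alpha: float = 0.05

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "band" in raw:
            raw["band"] = tuple(raw["band"])
        if "fit_range" in raw:
            raw["fit_range"] = tuple(raw["fit_range"])
        return cls(**raw)
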