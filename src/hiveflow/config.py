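"""Pipeline configuration.

Every tracking-derived constant of the analysis is a configurable default
here, never hard-coded at a call site: the 1 frame/s imaging rate, the
4.9 mm / 60 deg stationarity thresholds, the 60 s merge gap and 3 s / 180 s
duration bounds for trophallaxis events, the 20 mm proximity radius and
30-frame minimum interaction, the forager trip rule, the 20 s assay
consistency threshold, and the last-2-days analysis window.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # sampling and geometry
    fs: float = 1.0
    hive_width_mm: float = 448.0
    hive_height_mm: float = 232.0
    # kinematics
    min_displacement_mm: float = 4.9
    min_turn_deg: float = 60.0
    # trophallaxis event rules
    troph_max_gap_s: float = 60.0
    troph_min_s: float = 3.0
    troph_max_s: float = 180.0
    # proximity interactions
    r_max_mm: float = 20.0
    l_min_frames: int = 30
    # forager rule
    forager_min_total: int = 6
    forager_min_per_day: int = 4
    forager_min_days: int = 2
    forager_min_peak_fraction: float = 0.25
    peak_start: str = "10:00"
    peak_end: str = "15:00"
    # assay rule
    aggression_min_s: float = 20.0
    care_min_s: float = 20.0
    # analysis window: last N days of the recording (clamped to its span)
    window_days: float = 2.0
    # influence estimation
    var_order: str | int = "aic"
    var_p_max: int = 3
    n_freqs: int = 128
    pdc_variant: str = "info"
    # reproducibility
    seed: int = 0
    # inputs/outputs (paths; optional tables may be None)
    detections: str | None = None
    trophallaxis_raw: str | None = None
    trips: str | None = None
    assays: str | None = None
    genotypes: str | None = None
    effects: str | None = None
    outdir: str = "hiveflow_out"

    def __post_init__(self) -> None:
        positives = ["fs", "hive_width_mm", "hive_height_mm", "min_displacement_mm",
                     "min_turn_deg", "troph_max_gap_s", "troph_min_s", "troph_max_s",
                     "r_max_mm", "l_min_frames", "forager_min_total",
                     "forager_min_per_day", "forager_min_days",
                     "forager_min_peak_fraction", "aggression_min_s", "care_min_s",
                     "window_days", "var_p_max", "n_freqs"]
        for name in positives:
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name} must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a config; keys present in the file override the defaults."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    _PATH_FIELDS = ("detections", "trophallaxis_raw", "trips", "assays",
                    "genotypes", "effects", "outdir")

    def digest(self) -> str:
        """Stable hash of the analysis parameters, for the run manifest.

        I/O paths are excluded: the digest identifies what was computed, not
        where the tables happened to live.
        """
        data = {k: v for k, v in self.to_dict().items() if k not in self._PATH_FIELDS}
        blob = json.dumps(data, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
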