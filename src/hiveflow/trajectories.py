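"""Trajectory container shared by all stages.

Detections are per-frame barcode reads: one row per (bee, frame) with the
barcode-center position in millimetres and the body-axis orientation in
degrees.  The coordinate origin is the upper-left corner of the hive with y
increasing downward (the screen convention of the tracking imagery); frames
are 0-based integers sampled ``fs`` times per second.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DETECTION_COLUMNS = ["bee_id", "frame", "x_mm", "y_mm", "orientation_deg"]


@dataclass
class TrajectoryTable:
    """Per-frame positions/orientations of identified bees.

    Parameters
    ----------
    frames : pandas.DataFrame
        Columns ``bee_id, frame, x_mm, y_mm, orientation_deg``; at most one
        row per (bee_id, frame).
    fs : float
        Sampling rate of the imagery in frames per second (1 in the study).
    hive_width_mm, hive_height_mm : float
        Extent of the tracked arena; positions must lie inside.
    """

    frames: pd.DataFrame
    fs: float = 1.0
    hive_width_mm: float = 448.0
    hive_height_mm: float = 232.0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        missing = [c for c in DETECTION_COLUMNS if c not in self.frames.columns]
        if missing:
            raise ValueError(f"detection table missing columns: {missing}")
        self.frames = self.frames.sort_values(["bee_id", "frame"], kind="mergesort").reset_index(drop=True)

    def validate(self) -> list[str]:
        """Return a list of human-readable constraint violations (empty if valid)."""
        problems: list[str] = []
        df = self.frames
        dup = df.duplicated(subset=["bee_id", "frame"])
        for idx in df.index[dup]:
            problems.append(f"row {idx}: duplicate (bee_id, frame) = "
                            f"({df.at[idx, 'bee_id']}, {df.at[idx, 'frame']})")
        bad_x = (df["x_mm"] < 0) | (df["x_mm"] > self.hive_width_mm)
        bad_y = (df["y_mm"] < 0) | (df["y_mm"] > self.hive_height_mm)
        for idx in df.index[bad_x | bad_y]:
            problems.append(f"row {idx}: position ({df.at[idx, 'x_mm']:.2f}, "
                            f"{df.at[idx, 'y_mm']:.2f}) outside hive bounds")
        bad_o = (df["orientation_deg"] < 0) | (df["orientation_deg"] >= 360)
        for idx in df.index[bad_o]:
            problems.append(f"row {idx}: orientation {df.at[idx, 'orientation_deg']} "
                            "outside [0, 360)")
        return problems

    @property
    def bee_ids(self) -> np.ndarray:
        return np.sort(self.frames["bee_id"].unique())

    @property
    def frame_range(self) -> tuple[int, int]:
        return int(self.frames["frame"].min()), int(self.frames["frame"].max())

    def to_csv(self, path: str | Path) -> None:
        self.frames.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, fs: float = 1.0,
                 hive_width_mm: float = 448.0, hive_height_mm: float = 232.0) -> "TrajectoryTable":
        return cls(pd.read_csv(path), fs=fs, hive_width_mm=hive_width_mm,
                   hive_height_mm=hive_height_mm)

    def pivot_positions(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Dense (n_bees, n_frames) x/y arrays with NaN at missing detections.

        Returns ``(bee_ids, frame_index, x, y)`` where ``frame_index`` starts at
        the table's first frame.
        """
        f0, f1 = self.frame_range
        n_frames = f1 - f0 + 1
        bees = self.bee_ids
        bee_pos = {b: i for i, b in enumerate(bees)}
        x = np.full((len(bees), n_frames), np.nan)
        y = np.full((len(bees), n_frames), np.nan)
        bi = self.frames["bee_id"].map(bee_pos).to_numpy()
        fi = self.frames["frame"].to_numpy() - f0
        x[bi, fi] = self.frames["x_mm"].to_numpy()
        y[bi, fi] = self.frames["y_mm"].to_numpy()
        return bees, np.arange(f0, f1 + 1), x, y
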