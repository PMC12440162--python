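"""Instantaneous and mean movement speeds with stationarity filtering.

Linear speed is the Euclidean displacement of the barcode center between
consecutive frames divided by the inter-frame interval (1/fs seconds);
angular speed is the unsigned angle between the body-orientation vectors at
the two frames, wrapped to [0, 180] degrees, over the same interval.

Two rules suppress measurements: no speed is produced for frame t+1 when the
bee was undetected at frame t, and a frame pair in which the bee moved less
than one honeycomb-cell width (4.9 mm) AND turned less than one cell corner
(60 deg) yields ``recorded = False`` with no speed values — such small motions
are what a stationary bee performs while grooming or being groomed, not
locomotion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajectories import TrajectoryTable

SPEED_COLUMNS = ["bee_id", "frame", "linear_speed_mm_s", "angular_speed_deg_s", "recorded"]


@dataclass(frozen=True)
class KinematicThresholds:
    """Sub-threshold motion is treated as stationary, not locomotion."""

    min_displacement_mm: float = 4.9   # width of a honeycomb cell
    min_turn_deg: float = 60.0         # angle from one cell corner to the next

    def __post_init__(self) -> None:
        if self.min_displacement_mm <= 0 or self.min_turn_deg <= 0:
            raise ValueError("kinematic thresholds must be positive")


def wrap_angle_deg(delta: np.ndarray) -> np.ndarray:
    """Unsigned angle between two orientation vectors, in [0, 180]."""
    d = np.abs(np.asarray(delta, dtype=float)) % 360.0
    return np.minimum(d, 360.0 - d)


def instantaneous_speeds(traj: TrajectoryTable,
                         thresholds: KinematicThresholds = KinematicThresholds()) -> pd.DataFrame:
    """Per-frame speeds for every consecutive detected frame pair.

    Returns a table with one row per (bee, frame t+1) for which the bee was
    detected at both t and t+1.  ``recorded`` is False (and the speed columns
    NaN) when both the displacement and the turn are sub-threshold.

    Raises
    ------
    ValueError
        If the trajectory contains duplicate (bee_id, frame) keys.
    """
    df = traj.frames
    if df.duplicated(subset=["bee_id", "frame"]).any():
        raise ValueError("duplicate (bee_id, frame) keys in trajectory")
    if df.empty:
        return pd.DataFrame(columns=SPEED_COLUMNS)

    dt = 1.0 / traj.fs
    out = []
    for bee_id, g in df.groupby("bee_id", sort=True):
        frames = g["frame"].to_numpy()
        consecutive = np.diff(frames) == 1
        if not consecutive.any():
            continue
        dx = np.diff(g["x_mm"].to_numpy())[consecutive]
        dy = np.diff(g["y_mm"].to_numpy())[consecutive]
        dori = np.diff(g["orientation_deg"].to_numpy())[consecutive]
        disp = np.hypot(dx, dy)
        turn = wrap_angle_deg(dori)
        recorded = (disp >= thresholds.min_displacement_mm) | (turn >= thresholds.min_turn_deg)
        lin = np.where(recorded, disp / dt, np.nan)
        ang = np.where(recorded, turn / dt, np.nan)
        out.append(pd.DataFrame({
            "bee_id": bee_id,
            "frame": frames[1:][consecutive],
            "linear_speed_mm_s": lin,
            "angular_speed_deg_s": ang,
            "recorded": recorded,
        }))
    if not out:
        return pd.DataFrame(columns=SPEED_COLUMNS)
    return pd.concat(out, ignore_index=True)


def mean_speeds(records: pd.DataFrame,
                window: tuple[int, int] | None = None) -> pd.DataFrame:
    """Per-bee mean linear and angular speed over recorded measurements.

    ``window`` is an inclusive (start_frame, end_frame) interval applied to
    the record's frame (the later frame of each pair).  Bees with no recorded
    measurement in the window receive NaN means, never zero.
    """
    if records.empty:
        return pd.DataFrame(columns=["bee_id", "mean_linear_mm_s", "mean_angular_deg_s", "n_recorded"])
    df = records
    if window is not None:
        lo, hi = window
        if hi < lo:
            raise ValueError("empty window: end before start")
        df = df[(df["frame"] >= lo) & (df["frame"] <= hi)]

    all_bees = records["bee_id"].unique()
    rec = df[df["recorded"].astype(bool)]
    grouped = rec.groupby("bee_id").agg(
        mean_linear_mm_s=("linear_speed_mm_s", "mean"),
        mean_angular_deg_s=("angular_speed_deg_s", "mean"),
        n_recorded=("recorded", "size"),
    )
    result = grouped.reindex(all_bees)
    result["n_recorded"] = result["n_recorded"].fillna(0).astype(int)
    return result.rename_axis("bee_id").reset_index().sort_values("bee_id").reset_index(drop=True)
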