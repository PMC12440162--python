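"""Proximal-interaction extraction.

A proximal interaction is a contiguous run of frames in which a focal bee and
one neighbor are both detected, within R_max = 20 mm of each other
(about twice a bee's body length), both actively moving, and not engaged in
trophallaxis with each other, lasting at least L_min = 30 frames (30 s at
1 frame/s) so the paired coordinate series supports VAR estimation.  "Moving"
reuses the kinematic stationarity rule: a frame whose incoming speed pair was
suppressed (recorded = False) is a low-speed frame and breaks the run.

Every bee serves as focal in turn, so a physical encounter can contribute one
interaction for each participant.  When a focal bee meets the same neighbor
in several qualifying runs, only the first is kept, so the neighbor identity
varies across a focal bee's interactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trajectories import TrajectoryTable


@dataclass(frozen=True)
class ProximityParams:
    r_max_mm: float = 20.0
    l_min_frames: int = 30
    exclude_low_speed: bool = True
    exclude_trophallaxis: bool = True
    first_interaction_only: bool = True

    def __post_init__(self) -> None:
        if self.r_max_mm <= 0:
            raise ValueError("r_max_mm must be positive")
        if self.l_min_frames < 2:
            raise ValueError("l_min_frames must be at least 2")


@dataclass
class ProximityInteraction:
    """One qualifying run with the aligned coordinate series of both bees."""

    focal_id: object
    neighbor_id: object
    start_frame: int
    end_frame: int
    focal_x: np.ndarray = field(repr=False)
    focal_y: np.ndarray = field(repr=False)
    neighbor_x: np.ndarray = field(repr=False)
    neighbor_y: np.ndarray = field(repr=False)

    @property
    def length(self) -> int:
        return self.end_frame - self.start_frame + 1


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, end) index pairs, inclusive."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return [(int(s), int(e - 1)) for s, e in zip(edges[::2], edges[1::2])]


def find_proximity_interactions(traj: TrajectoryTable,
                                events: pd.DataFrame | None = None,
                                speeds: pd.DataFrame | None = None,
                                params: ProximityParams = ProximityParams(),
                                ) -> dict[object, list[ProximityInteraction]]:
    """Extract proximal interactions for every bee acting as focal.

    Parameters
    ----------
    traj : TrajectoryTable
    events : DataFrame or None
        Filtered trophallaxis events; frames inside an event of the focal /
        neighbor pair are excluded.  ``None`` is treated as no events.
    speeds : DataFrame or None
        Output of :func:`hiveflow.kinematics.instantaneous_speeds`; required
        when ``params.exclude_low_speed`` is set.
    """
    if params.exclude_low_speed and speeds is None:
        raise ValueError("speed table required to exclude low-speed frames; "
                         "pass speeds= or set exclude_low_speed=False")

    bees, frame_index, x, y = traj.pivot_positions()
    f0 = int(frame_index[0])
    n_frames = len(frame_index)
    bee_pos = {b: i for i, b in enumerate(bees)}

    low = np.zeros((len(bees), n_frames), dtype=bool)
    if params.exclude_low_speed and speeds is not None and not speeds.empty:
        ns = speeds[~speeds["recorded"].astype(bool)]
        bi = ns["bee_id"].map(bee_pos).to_numpy()
        fi = ns["frame"].to_numpy() - f0
        ok = (fi >= 0) & (fi < n_frames)
        low[bi[ok], fi[ok]] = True

    troph: dict[tuple, np.ndarray] = {}
    if params.exclude_trophallaxis and events is not None and not events.empty:
        for row in events.itertuples(index=False):
            key = (row.bee_a, row.bee_b) if row.bee_a < row.bee_b else (row.bee_b, row.bee_a)
            m = troph.setdefault(key, np.zeros(n_frames, dtype=bool))
            s = max(int(row.start_frame) - f0, 0)
            e = min(int(row.end_frame) - f0, n_frames - 1)
            if e >= s:
                m[s:e + 1] = True

    detected = np.isfinite(x)
    r2 = params.r_max_mm ** 2
    result: dict[object, list[ProximityInteraction]] = {b: [] for b in bees}
    for i, focal in enumerate(bees):
        for j, nb in enumerate(bees):
            if i == j:
                continue
            mask = detected[i] & detected[j]
            if not mask.any():
                continue
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            with np.errstate(invalid="ignore"):
                mask &= (dx * dx + dy * dy) <= r2
            mask &= ~low[i] & ~low[j]
            key = (focal, nb) if focal < nb else (nb, focal)
            if key in troph:
                mask &= ~troph[key]
            for s, e in _runs(mask):
                if e - s + 1 < params.l_min_frames:
                    continue
                result[focal].append(ProximityInteraction(
                    focal_id=focal, neighbor_id=nb,
                    start_frame=int(frame_index[s]), end_frame=int(frame_index[e]),
                    focal_x=x[i, s:e + 1].copy(), focal_y=y[i, s:e + 1].copy(),
                    neighbor_x=x[j, s:e + 1].copy(), neighbor_y=y[j, s:e + 1].copy(),
                ))
                if params.first_interaction_only:
                    break  # runs are scanned in time order; keep the earliest
    return result


def build_bivariate_series(interaction: ProximityInteraction, axis: str) -> tuple[np.ndarray, np.ndarray]:
    """Paired (focal, neighbor) coordinate series for one axis.

    Raw coordinates, no detrending; first series is the focal bee's.
    """
    if axis.upper() == "X":
        return interaction.focal_x, interaction.neighbor_x
    if axis.upper() == "Y":
        return interaction.focal_y, interaction.neighbor_y
    raise ValueError(f"axis must be 'X' or 'Y', got {axis!r}")


def interaction_index(interactions: dict[object, list[ProximityInteraction]]) -> pd.DataFrame:
    """Flat index table (focal, neighbor, start, end, length) of all interactions."""
    rows = [
        (it.focal_id, it.neighbor_id, it.start_frame, it.end_frame, it.length)
        for lst in interactions.values() for it in lst
    ]
    return pd.DataFrame(rows, columns=["focal_id", "neighbor_id", "start_frame", "end_frame", "length"])
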