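"""Trophallaxis event processing: merge, duration filter, per-bee frequency.

Raw detector output fragments a single food-sharing bout into several short
intervals whenever the mouth-to-mouth contact is briefly lost.  Fragments of
the same unordered pair are therefore merged when consecutive and separated
by less than one minute.  Merged events shorter than 3 s are discarded (too
short for liquid transfer) and events longer than 3 min are removed as
spurious detections.  The per-bee frequency of the surviving events, averaged
over an analysis window, is the sociability measure.

Event tables use canonical pair ordering: ``bee_a < bee_b``.  Frame intervals
are inclusive, so an event spanning frames [s, e] lasts (e - s + 1)/fs
seconds: a single-frame event at fs = 1 lasts one second, not zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

EVENT_COLUMNS = ["bee_a", "bee_b", "start_frame", "end_frame"]


def _canonicalize(events: pd.DataFrame) -> pd.DataFrame:
    """Sort each pair so bee_a < bee_b; validate intervals."""
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")
    df = events.copy()
    if (df["start_frame"] > df["end_frame"]).any():
        raise ValueError("event with start_frame > end_frame")
    if (df["bee_a"] == df["bee_b"]).any():
        raise ValueError("event pairing a bee with itself")
    swap = df["bee_a"] > df["bee_b"]
    df.loc[swap, ["bee_a", "bee_b"]] = df.loc[swap, ["bee_b", "bee_a"]].to_numpy()
    return df


def merge_raw_events(raw: pd.DataFrame, fs: float = 1.0, max_gap_s: float = 60.0) -> pd.DataFrame:
    """Union consecutive same-pair events separated by less than ``max_gap_s``.

    Merging is transitive and per unordered pair: events are sorted by start
    frame and chained whenever the gap between one event's end and the next
    event's start is below the threshold; overlapping events are unioned the
    same way.  The merged interval spans min start to max end.
    """
    if raw.empty:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    df = _canonicalize(raw)
    max_gap_frames = max_gap_s * fs
    rows = []
    for (a, b), g in df.groupby(["bee_a", "bee_b"], sort=True):
        g = g.sort_values(["start_frame", "end_frame"])
        starts = g["start_frame"].to_numpy()
        ends = g["end_frame"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s - cur_e < max_gap_frames:
                cur_e = max(cur_e, e)
            else:
                rows.append((a, b, cur_s, cur_e))
                cur_s, cur_e = s, e
        rows.append((a, b, cur_s, cur_e))
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def filter_events(merged: pd.DataFrame, fs: float = 1.0,
                  min_s: float = 3.0, max_s: float = 180.0) -> pd.DataFrame:
    """Keep merged events with duration in [min_s, max_s] (boundaries inclusive).

    Adds a ``duration_s`` column computed from the inclusive frame span.
    """
    if merged.empty:
        return pd.DataFrame(columns=EVENT_COLUMNS + ["duration_s"])
    df = merged.copy()
    df["duration_s"] = (df["end_frame"] - df["start_frame"] + 1) / fs
    keep = (df["duration_s"] >= min_s) & (df["duration_s"] <= max_s)
    return df[keep].reset_index(drop=True)


def trophallaxis_frequency(events: pd.DataFrame, window: tuple[int, int],
                           fs: float = 1.0,
                           bee_ids: list | np.ndarray | None = None) -> pd.DataFrame:
    """Per-bee mean events/day over an analysis window.

    An event is assigned to the window by its start frame; each event credits
    both partners once.  ``bee_ids`` extends the output to bees with zero
    events (frequency 0).  The number of days is the window's inclusive frame
    span divided by fs * 86400.
    """
    lo, hi = window
    if hi < lo:
        raise ValueError("empty analysis window")
    n_days = (hi - lo + 1) / (fs * 86400.0)
    if events.empty:
        in_win = events
    else:
        in_win = events[(events["start_frame"] >= lo) & (events["start_frame"] <= hi)]
    counts: dict = {}
    for col in ("bee_a", "bee_b"):
        if not in_win.empty:
            for bee, n in in_win[col].value_counts().items():
                counts[bee] = counts.get(bee, 0) + int(n)
    ids = set(counts)
    if bee_ids is not None:
        ids |= set(bee_ids)
    out = pd.DataFrame({
        "bee_id": sorted(ids),
        "n_events": [counts.get(b, 0) for b in sorted(ids)],
    })
    out["trophallaxis_per_day"] = out["n_events"] / n_days
    return out
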