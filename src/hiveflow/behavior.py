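"""Rule-based behavioral-state classification.

Bees are assigned exactly one of six division-of-labor states from the
entrance-monitor trip log and the dish-assay observations:

* forager — enough verified foraging trips (see :func:`classify_forager`);
* guard — consistent aggression (biting + stinging >= 20 s) toward an
  intruder, as the only qualifying behavior;
* nurse — consistent larval feeding (>= 20 s), as the only qualifying
  behavior;
* generalist — two or more of {aggression, brood care, foraging};
* non_responder — no response of any kind to either stimulus and no trips;
* baseline — responsive (some activity, or fanning/wax-building/vibration
  signaling) but below every qualifying threshold.

The thresholds are configurable; the defaults take the permissive end of the
20-30 s consistency criterion.  Aggression sums biting and stinging; brood
care is larval feeding (inspection and the other behaviors count toward
responsiveness only).
"""

from __future__ import annotations

import datetime as _dt

import numpy as np
import pandas as pd

BEHAVIOR_LABELS = ("generalist", "forager", "nurse", "guard", "non_responder", "baseline")

AGGRESSION_BEHAVIORS = ("bite", "sting")
CARE_BEHAVIORS = ("feed",)
OTHER_BEHAVIORS = ("inspect", "fan", "wax", "vibrate")


def _parse_time(value) -> _dt.time:
    if isinstance(value, _dt.time):
        return value
    if isinstance(value, _dt.datetime):
        return value.time()
    return _dt.time.fromisoformat(str(value))


def classify_forager(trips: pd.DataFrame,
                     peak_start: str = "10:00", peak_end: str = "15:00",
                     min_total: int = 6, min_per_day: int = 4,
                     min_days: int = 2, min_peak_fraction: float = 0.25,
                     bee_ids=None) -> pd.DataFrame:
    """Apply the forager trip rule to an entrance-monitor trip log.

    A bee is a forager iff it took at least ``min_total`` trips overall, at
    least ``min_days`` distinct days each had more than three trips (i.e.
    >= ``min_per_day``), and at least ``min_peak_fraction`` of all its trips
    started during peak foraging hours (peak bounds inclusive).

    Returns a table with the flag and the supporting evidence columns.
    """
    t0, t1 = _parse_time(peak_start), _parse_time(peak_end)
    ids = set() if bee_ids is None else set(np.asarray(bee_ids).tolist())
    rows = []
    if not trips.empty:
        for col in ("bee_id", "date", "time"):
            if col not in trips.columns:
                raise ValueError(f"trip table missing column {col!r}")
        ids |= set(trips["bee_id"].unique())
    for bee in sorted(ids):
        g = trips[trips["bee_id"] == bee] if not trips.empty else trips
        total = len(g)
        if total == 0:
            rows.append((bee, 0, 0, 0.0, False))
            continue
        per_day = g.groupby("date").size()
        qualifying_days = int((per_day >= min_per_day).sum())
        times = g["time"].map(_parse_time)
        peak = int(((times >= t0) & (times <= t1)).sum())
        frac = peak / total
        flag = (total >= min_total) and (qualifying_days >= min_days) and (frac >= min_peak_fraction)
        rows.append((bee, total, qualifying_days, frac, bool(flag)))
    return pd.DataFrame(rows, columns=["bee_id", "n_trips", "n_qualifying_days",
                                       "peak_fraction", "forager"])


def classify_states(assays: pd.DataFrame, forager_flags: pd.DataFrame | dict,
                    aggression_min_s: float = 20.0, care_min_s: float = 20.0,
                    ) -> pd.DataFrame:
    """Assign one behavioral state per bee from assays and forager flags.

    ``forager_flags`` is either the output of :func:`classify_forager` or a
    plain bee -> bool mapping.  Bees present in the flags but missing from
    the assay table are returned unlabeled with a diagnostic note.
    """
    if isinstance(forager_flags, pd.DataFrame):
        flags = dict(zip(forager_flags["bee_id"], forager_flags["forager"].astype(bool)))
    else:
        flags = {b: bool(v) for b, v in forager_flags.items()}

    agg_s: dict = {}
    care_s: dict = {}
    other_s: dict = {}
    assay_bees: set = set()
    if not assays.empty:
        assay_bees = set(assays["bee_id"].unique())
        for row in assays.itertuples(index=False):
            d = float(row.total_duration_s)
            if row.behavior in AGGRESSION_BEHAVIORS:
                agg_s[row.bee_id] = agg_s.get(row.bee_id, 0.0) + d
            elif row.behavior in CARE_BEHAVIORS:
                care_s[row.bee_id] = care_s.get(row.bee_id, 0.0) + d
            elif row.behavior in OTHER_BEHAVIORS:
                other_s[row.bee_id] = other_s.get(row.bee_id, 0.0) + d
            else:
                raise ValueError(f"unknown assay behavior {row.behavior!r}")

    rows = []
    for bee in sorted(assay_bees | set(flags)):
        if bee not in assay_bees:
            rows.append((bee, None, np.nan, np.nan, np.nan, flags.get(bee, False),
                         "missing from assay table"))
            continue
        a = agg_s.get(bee, 0.0)
        c = care_s.get(bee, 0.0)
        o = other_s.get(bee, 0.0)
        f = flags.get(bee, False)
        qualifying = int(a >= aggression_min_s) + int(c >= care_min_s) + int(f)
        if qualifying >= 2:
            label = "generalist"
        elif a >= aggression_min_s:
            label = "guard"
        elif c >= care_min_s:
            label = "nurse"
        elif f:
            label = "forager"
        elif a == 0.0 and c == 0.0 and o == 0.0:
            label = "non_responder"
        else:
            label = "baseline"
        rows.append((bee, label, a, c, o, f, ""))
    return pd.DataFrame(rows, columns=["bee_id", "label", "aggression_s", "care_s",
                                       "other_s", "forager", "note"])
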