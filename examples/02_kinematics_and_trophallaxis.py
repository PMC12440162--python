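"""Movement kinematics and trophallaxis-based sociability on one colony.

Instantaneous speeds apply the stationarity rule (no measurement when a bee
moved < 4.9 mm and turned < 60 degrees); raw trophallaxis fragments are
merged when < 60 s apart and kept when lasting 3 s to 3 min; the per-bee
event frequency over the analysis window is the sociability score.
"""

import pandas as pd

from hiveflow import (TrajectoryTable, instantaneous_speeds, mean_speeds,
                      merge_raw_events, filter_events, trophallaxis_frequency)
from hiveflow.datasets import make_demo_colony

paths = make_demo_colony("scratch/example_colony", seed=0)
traj = TrajectoryTable.from_csv(paths["detections"], hive_width_mm=120, hive_height_mm=70)
raw = pd.read_csv(paths["trophallaxis_raw"])

speeds = instantaneous_speeds(traj)
means = mean_speeds(speeds)
print(f"speed records: {len(speeds)}, recorded fraction: {speeds['recorded'].mean():.2f}")
print(f"mean linear speed across bees: {means['mean_linear_mm_s'].mean():.1f} mm/s")

events = filter_events(merge_raw_events(raw))
freq = trophallaxis_frequency(events, window=traj.frame_range, bee_ids=traj.bee_ids)
print(f"{len(raw)} raw fragments -> {len(events)} filtered events")
print(f"trophallaxis frequency (events/day): mean {freq['trophallaxis_per_day'].mean():.1f}, "
      f"range {freq['trophallaxis_per_day'].min():.0f}-{freq['trophallaxis_per_day'].max():.0f}")
# The frequency is the sociability phenotype: how often a bee shares food,
# normalized per day of recording.
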