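import numpy as np
import pandas as pd
import pytest

from hiveflow import TrajectoryTable


def make_traj(rows, fs=1.0, width=448.0, height=232.0):
    """Build a TrajectoryTable from (bee_id, frame, x, y, orientation) tuples."""
    df = pd.DataFrame(rows, columns=["bee_id", "frame", "x_mm", "y_mm", "orientation_deg"])
    return TrajectoryTable(df, fs=fs, hive_width_mm=width, hive_height_mm=height)


def co_walking_pair(n_frames, separation_mm=15.0, step_mm=10.0, start_x=10.0, y=50.0):
    """Two bees advancing together at supra-threshold speed, fixed separation."""
    rows = []
    for t in range(n_frames):
        x = start_x + step_mm * t
        rows.append((0, t, x, y, 0.0))
        rows.append((1, t, x, y + separation_mm, 0.0))
    return rows


@pytest.fixture(scope="session")
def demo_colony(tmp_path_factory):
    """The packaged synthetic fixture: 20 bees, 2 simulated hours, seed 0."""
    from hiveflow.datasets import make_demo_colony

    outdir = tmp_path_factory.mktemp("demo_colony")
    paths = make_demo_colony(outdir, seed=0)
    return paths
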