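"""Assembled synthetic-colony fixtures.

Bundles the individual generators into a coherent small colony: coupled
trajectories, raw trophallaxis detections (fragmented from the injected
episodes so the merge rule has work to do), a trip log and assay table
consistent with per-bee ground-truth labels, and a genotype matrix with
effect sizes.  Everything is written as plain CSV plus a JSON ground-truth
sidecar and a ready-to-run pipeline config.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .behavior import BEHAVIOR_LABELS
from .config import PipelineConfig
from .simulate import (ColonySimParams, simulate_assay, simulate_genotypes,
                       simulate_trajectories, simulate_trip_log)


def fragment_events(events: pd.DataFrame, fs: float = 1.0, seed: int = 0,
                    max_gap_s: float = 30.0) -> pd.DataFrame:
    """Split episodes into 'raw' detector fragments with sub-minute gaps.

    Each injected episode longer than ~10 s is cut into two fragments
    separated by a gap below the merge threshold, so merging reconstructs the
    original interval exactly.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for ev in events.itertuples(index=False):
        start, end = int(ev.start_frame), int(ev.end_frame)
        span = end - start + 1
        gap = int(min(max_gap_s * fs, max(span // 4, 2)))
        if span >= 10 * fs and span > gap + 4:
            cut = start + int(rng.integers(2, span - gap - 2))
            rows.append((ev.bee_a, ev.bee_b, start, cut))
            rows.append((ev.bee_a, ev.bee_b, cut + gap, end))
        else:
            rows.append((ev.bee_a, ev.bee_b, start, end))
    return pd.DataFrame(rows, columns=["bee_a", "bee_b", "start_frame", "end_frame"])


def make_demo_colony(outdir: str | Path, n_bees: int = 20, n_frames: int = 7200,
                     fs: float = 1.0, hive_width_mm: float = 120.0,
                     hive_height_mm: float = 70.0, n_coupled_pairs: int = 4,
                     coupling: float = 0.6, n_days: int = 4, n_snps: int = 100,
                     seed: int = 0) -> dict[str, Path]:
    """Write a complete ground-truthed colony fixture under ``outdir``.

    The default 20 bees in a 120 x 70 mm arena over 2 simulated hours give a
    bee density comparable to a crowded comb, so proximity encounters are
    frequent enough that every bee accumulates interactions.

    Returns a name -> path mapping; also writes ``ground_truth.json`` and a
    pipeline ``config.yaml`` pointing at the generated tables.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    pair_pool = rng.permutation(n_bees)
    pairs = {}
    for i in range(min(n_coupled_pairs, n_bees // 2)):
        leader, follower = int(pair_pool[2 * i]), int(pair_pool[2 * i + 1])
        pairs[(leader, follower)] = coupling
    params = ColonySimParams(
        n_bees=n_bees, n_frames=n_frames, fs=fs,
        hive_width_mm=hive_width_mm, hive_height_mm=hive_height_mm,
        coupling=pairs, seed=seed)
    traj, truth = simulate_trajectories(params)

    raw_events = fragment_events(truth.trophallaxis_events, fs=fs, seed=seed + 1)

    labels = {b: BEHAVIOR_LABELS[b % len(BEHAVIOR_LABELS)] for b in range(n_bees)}
    forager_ids = {b for b, lab in labels.items() if lab == "forager"}
    zero_trip_ids = {b for b, lab in labels.items() if lab == "non_responder"}
    trips, trip_truth = simulate_trip_log(n_bees, n_days, forager_ids,
                                          seed=seed + 2, zero_trip_ids=zero_trip_ids)
    assays = simulate_assay(n_bees, labels, seed=seed + 3)

    effects = rng.normal(0.0, 0.3, n_snps)
    genotypes, geno_truth = simulate_genotypes(n_bees, n_snps, effects, seed=seed + 4)
    effects_df = pd.DataFrame({"snp_id": [c for c in genotypes.columns if c != "bee_id"],
                               "beta": effects})

    paths = {
        "detections": outdir / "detections.csv",
        "trophallaxis_raw": outdir / "trophallaxis_raw.csv",
        "trips": outdir / "trips.csv",
        "assays": outdir / "assays.csv",
        "genotypes": outdir / "genotypes.csv",
        "effects": outdir / "effects.csv",
    }
    traj.to_csv(paths["detections"])
    raw_events.to_csv(paths["trophallaxis_raw"], index=False)
    trips.to_csv(paths["trips"], index=False)
    assays.to_csv(paths["assays"], index=False)
    genotypes.to_csv(paths["genotypes"], index=False)
    effects_df.to_csv(paths["effects"], index=False)

    ground_truth = {
        "coupling": [[l, f, c] for (l, f), c in pairs.items()],
        "labels": {str(b): lab for b, lab in labels.items()},
        "forager_clause_violations": {str(b): v for b, v in
                                      trip_truth.forager_clause_violations.items()},
        "prs": {str(b): v for b, v in geno_truth.prs.items()},
        "n_injected_trophallaxis_events": int(len(truth.trophallaxis_events)),
    }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(ground_truth, fh, indent=2, sort_keys=True)
    paths["ground_truth"] = outdir / "ground_truth.json"

    cfg = PipelineConfig(
        fs=fs, hive_width_mm=hive_width_mm, hive_height_mm=hive_height_mm,
        seed=seed,
        detections=str(paths["detections"]),
        trophallaxis_raw=str(paths["trophallaxis_raw"]),
        trips=str(paths["trips"]),
        assays=str(paths["assays"]),
        genotypes=str(paths["genotypes"]),
        effects=str(paths["effects"]),
        outdir=str(outdir / "results"))
    cfg.to_yaml(outdir / "config.yaml")
    paths["config"] = outdir / "config.yaml"
    return paths
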