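"""End-to-end runner and table validation.

Stages run in dependency order: kinematics -> trophallaxis -> proximity ->
influence -> behavioral states -> association, joined into a single per-bee
table (sociability score, mean speeds, bidirectional information flow,
behavioral label, and polygenic score when genotypes are supplied).  A
machine-readable run manifest records the configuration hash, the seed, and
per-stage row counts; reruns with the same inputs and configuration produce
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .association import polygenic_score
from .behavior import classify_forager, classify_states
from .config import PipelineConfig
from .influence import InfluenceSettings, social_influence_table
from .kinematics import KinematicThresholds, instantaneous_speeds, mean_speeds
from .proximity import ProximityParams, find_proximity_interactions, interaction_index
from .trajectories import TrajectoryTable, DETECTION_COLUMNS
from .trophallaxis import EVENT_COLUMNS, filter_events, merge_raw_events, trophallaxis_frequency

log = logging.getLogger("hiveflow")

SCHEMAS: dict[str, dict] = {
    "detections": {
        "columns": {"bee_id": "int", "frame": "int", "x_mm": "float",
                    "y_mm": "float", "orientation_deg": "float"},
        "unique": ["bee_id", "frame"],
    },
    "trophallaxis_raw": {
        "columns": {"bee_a": "int", "bee_b": "int",
                    "start_frame": "int", "end_frame": "int"},
    },
    "trips": {
        "columns": {"bee_id": "int", "date": "str", "time": "str"},
    },
    "assays": {
        "columns": {"bee_id": "int", "assay": "str", "behavior": "str",
                    "total_duration_s": "float"},
    },
    "effects": {
        "columns": {"snp_id": "str", "beta": "float"},
        "unique": ["snp_id"],
    },
}

_KIND_CHECKS = {
    "int": pd.api.types.is_integer_dtype,
    "float": pd.api.types.is_numeric_dtype,
    "str": lambda dt: pd.api.types.is_object_dtype(dt) or pd.api.types.is_string_dtype(dt),
}


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix in (".parquet", ".pq"):
        return pd.read_parquet(path)
    return pd.read_csv(path)


def validate_tables(paths: dict[str, str | Path],
                    schemas: dict[str, dict] = SCHEMAS,
                    config: PipelineConfig | None = None) -> list[str]:
    """Validate input tables against the published schemas.

    Checks column presence and types, key uniqueness, coordinate bounds and
    orientation range (for detections).  Returns a list of violation
    messages; an empty list means every table validated.
    """
    config = config or PipelineConfig()
    report: list[str] = []
    for name, path in paths.items():
        if name not in schemas:
            report.append(f"{name}: no schema defined")
            continue
        try:
            df = _read_table(path)
        except Exception as exc:  # unreadable file
            report.append(f"{name} ({path}): unreadable: {exc}")
            continue
        schema = schemas[name]
        for col, kind in schema["columns"].items():
            if col not in df.columns:
                report.append(f"{name}: missing column {col!r}")
            elif not df.empty and not _KIND_CHECKS[kind](df[col].dtype):
                report.append(f"{name}: column {col!r} has dtype {df[col].dtype}, expected {kind}")
        if any(c not in df.columns for c in schema["columns"]):
            continue
        if "unique" in schema:
            dup = df.duplicated(subset=schema["unique"])
            for idx in df.index[dup]:
                report.append(f"{name}: row {idx}: duplicate key "
                              f"{tuple(df.loc[idx, schema['unique']])}")
        if name == "detections" and not df.empty:
            traj = TrajectoryTable(df[DETECTION_COLUMNS], fs=config.fs,
                                   hive_width_mm=config.hive_width_mm,
                                   hive_height_mm=config.hive_height_mm)
            report.extend(f"detections: {msg}" for msg in traj.validate())
        if name == "trophallaxis_raw" and not df.empty:
            bad = df["start_frame"] > df["end_frame"]
            for idx in df.index[bad]:
                report.append(f"{name}: row {idx}: start_frame after end_frame")
    return report


def _analysis_window(traj: TrajectoryTable, config: PipelineConfig) -> tuple[int, int]:
    """Last ``window_days`` of the recording, clamped to the recorded span."""
    f0, f1 = traj.frame_range
    span = int(round(config.window_days * 86400 * config.fs))
    return max(f0, f1 - span + 1), f1


def run_pipeline(config: PipelineConfig, write: bool = True) -> dict:
    """Execute every stage and return the result bundle.

    Returns a dict with the per-bee table, per-stage intermediates, and the
    run manifest.  When ``write`` is set, tables are written as CSV under
    ``config.outdir`` together with ``manifest.json``.
    """
    if config.detections is None:
        raise ValueError("config.detections is required")
    traj = TrajectoryTable.from_csv(config.detections, fs=config.fs,
                                    hive_width_mm=config.hive_width_mm,
                                    hive_height_mm=config.hive_height_mm)
    problems = traj.validate()
    if problems:
        raise ValueError("detections failed validation:\n" + "\n".join(problems))
    window = _analysis_window(traj, config)
    counts = {"detections": len(traj.frames)}
    bees = traj.bee_ids

    # kinematics
    thresholds = KinematicThresholds(config.min_displacement_mm, config.min_turn_deg)
    speeds = instantaneous_speeds(traj, thresholds)
    means = mean_speeds(speeds, window=window)
    counts["speed_records"] = len(speeds)

    # trophallaxis
    if config.trophallaxis_raw is not None:
        raw = _read_table(config.trophallaxis_raw)
        merged = merge_raw_events(raw, fs=config.fs, max_gap_s=config.troph_max_gap_s)
        events = filter_events(merged, fs=config.fs, min_s=config.troph_min_s,
                               max_s=config.troph_max_s)
    else:
        raw = pd.DataFrame(columns=EVENT_COLUMNS)
        events = filter_events(raw, fs=config.fs)
        warnings.warn("no trophallaxis table supplied; sociability scores will be zero")
    freq = trophallaxis_frequency(events, window=window, fs=config.fs, bee_ids=bees)
    counts["trophallaxis_raw"] = len(raw)
    counts["trophallaxis_filtered"] = len(events)

    # strict conservation re-check: every filtered event in the window credits
    # exactly two bees
    lo, hi = window
    in_win = events[(events["start_frame"] >= lo) & (events["start_frame"] <= hi)] if not events.empty else events
    assert int(freq["n_events"].sum()) == 2 * len(in_win), "trophallaxis double-count identity violated"

    # proximity + influence, restricted to the analysis window
    win_frames = traj.frames[(traj.frames["frame"] >= lo) & (traj.frames["frame"] <= hi)]
    win_traj = TrajectoryTable(win_frames, fs=config.fs,
                               hive_width_mm=config.hive_width_mm,
                               hive_height_mm=config.hive_height_mm)
    params = ProximityParams(r_max_mm=config.r_max_mm, l_min_frames=config.l_min_frames)
    interactions = find_proximity_interactions(win_traj, events=events, speeds=speeds,
                                               params=params)
    idx = interaction_index(interactions)
    counts["proximity_interactions"] = len(idx)
    settings = InfluenceSettings(order=config.var_order, p_max=config.var_p_max,
                                 n_freqs=config.n_freqs, fs=config.fs,
                                 variant=config.pdc_variant)
    influence, influence_notes = social_influence_table(interactions, settings)
    counts["influence_rows"] = len(influence)

    # behavioral states
    if config.trips is not None:
        trips = _read_table(config.trips)
        flags = classify_forager(trips, peak_start=config.peak_start,
                                 peak_end=config.peak_end,
                                 min_total=config.forager_min_total,
                                 min_per_day=config.forager_min_per_day,
                                 min_days=config.forager_min_days,
                                 min_peak_fraction=config.forager_min_peak_fraction,
                                 bee_ids=bees)
    else:
        warnings.warn("no trip log supplied; labels restricted to assay-derivable states")
        log.warning("no trip log supplied; forager detection disabled")
        flags = pd.DataFrame({"bee_id": bees, "n_trips": 0, "n_qualifying_days": 0,
                              "peak_fraction": 0.0, "forager": False})
    if config.assays is not None:
        assays = _read_table(config.assays)
        labels = classify_states(assays, flags,
                                 aggression_min_s=config.aggression_min_s,
                                 care_min_s=config.care_min_s)
    else:
        labels = pd.DataFrame({"bee_id": bees, "label": None})
    counts["labeled_bees"] = int(labels["label"].notna().sum())

    # association
    prs = None
    if config.genotypes is not None and config.effects is not None:
        dosages = _read_table(config.genotypes)
        effects = _read_table(config.effects)
        prs = polygenic_score(dosages, effects)
        prs.index = dosages["bee_id"] if "bee_id" in dosages.columns else prs.index
        counts["scored_bees"] = len(prs)

    per_bee = pd.DataFrame({"bee_id": bees})
    per_bee = per_bee.merge(freq[["bee_id", "trophallaxis_per_day"]], on="bee_id", how="left")
    per_bee = per_bee.merge(means, on="bee_id", how="left")
    if not influence.empty:
        per_bee = per_bee.merge(influence, on="bee_id", how="left")
    else:
        for col in ("i_flow_out_bits", "i_flow_in_bits"):
            per_bee[col] = np.nan
        per_bee["n_interactions"] = 0
    per_bee = per_bee.merge(labels[["bee_id", "label"]], on="bee_id", how="left")
    if prs is not None:
        per_bee = per_bee.merge(prs.rename("polygenic_score").rename_axis("bee_id").reset_index(),
                                on="bee_id", how="left")
    per_bee = per_bee.sort_values("bee_id").reset_index(drop=True)

    manifest = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "analysis_window": list(window),
        "row_counts": counts,
        "influence_diagnostics": influence_notes,
    }
    bundle = {
        "per_bee": per_bee,
        "speeds": speeds,
        "mean_speeds": means,
        "events": events,
        "sociability": freq,
        "interactions": idx,
        "influence": influence,
        "labels": labels,
        "manifest": manifest,
    }
    if write:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("per_bee", "speeds", "mean_speeds", "events", "sociability",
                     "interactions", "influence", "labels"):
            bundle[name].to_csv(outdir / f"{name}.csv", index=False)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        log.info("pipeline complete: %s", json.dumps(counts))
    return bundle
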