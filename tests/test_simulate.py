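import numpy as np
import pandas as pd
import pytest

from hiveflow import (ColonySimParams, simulate_trajectories, simulate_var,
                      simulate_coupled_pair, simulate_trip_log, simulate_assay,
                      simulate_genotypes, polygenic_score, classify_forager)


class TestSimulateTrajectories:
    def test_seeded_determinism(self):
        p = ColonySimParams(n_bees=5, n_frames=300, seed=11)
        t1, g1 = simulate_trajectories(p)
        t2, g2 = simulate_trajectories(p)
        pd.testing.assert_frame_equal(t1.frames, t2.frames)
        pd.testing.assert_frame_equal(g1.trophallaxis_events, g2.trophallaxis_events)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ColonySimParams(n_bees=1, n_frames=10)
        with pytest.raises(ValueError):
            ColonySimParams(n_bees=3, n_frames=10, hive_width_mm=-1)
        with pytest.raises(ValueError):
            ColonySimParams(n_bees=3, n_frames=10, coupling={(0, 7): 0.5})
        with pytest.raises(ValueError):
            ColonySimParams(n_bees=3, n_frames=10, coupling={(0, 1): 1.2})

    def test_positions_within_bounds(self):
        p = ColonySimParams(n_bees=6, n_frames=1000, hive_width_mm=100,
                            hive_height_mm=60, seed=2)
        traj, _ = simulate_trajectories(p)
        assert traj.frames["x_mm"].between(0, 100).all()
        assert traj.frames["y_mm"].between(0, 60).all()
        assert traj.frames["orientation_deg"].between(0, 360, inclusive="left").all()

    def test_dropout_rate(self):
        p = ColonySimParams(n_bees=5, n_frames=4000, dropout_prob=0.2, seed=3)
        traj, _ = simulate_trajectories(p)
        rate = len(traj.frames) / (5 * 4000)
        assert rate == pytest.approx(0.8, abs=0.02)

    def test_uncoupled_pairs_have_no_lagged_cross_correlation(self):
        # colony defaults, no coupling: lag-1 cross-correlation of
        # displacement between any ordered pair stays near zero
        p = ColonySimParams(n_bees=10, n_frames=10_000, hive_width_mm=120,
                            hive_height_mm=70, dropout_prob=0.0, seed=3)
        traj, _ = simulate_trajectories(p)
        piv = traj.frames.pivot_table(index="frame", columns="bee_id", values="x_mm")
        dx = piv.diff().iloc[1:].to_numpy()
        worst = 0.0
        for i in range(10):
            for j in range(10):
                if i != j:
                    r = np.corrcoef(dx[:-1, i], dx[1:, j])[0, 1]
                    worst = max(worst, abs(r))
        assert worst < 0.05

    def test_coupling_induces_lagged_cross_correlation(self):
        p = ColonySimParams(n_bees=4, n_frames=10_000, hive_width_mm=200,
                            hive_height_mm=120, dropout_prob=0.0,
                            coupling={(0, 1): 0.5}, seed=6)
        traj, truth = simulate_trajectories(p)
        piv = traj.frames.pivot_table(index="frame", columns="bee_id", values="x_mm")
        dx = piv.diff().iloc[1:].to_numpy()
        # independent check: plain Pearson correlation of (leader t-1, follower t)
        r_fwd = np.corrcoef(dx[:-1, 0], dx[1:, 1])[0, 1]
        r_rev = np.corrcoef(dx[:-1, 1], dx[1:, 0])[0, 1]
        assert r_fwd > 0.15
        assert r_fwd > r_rev + 0.1
        assert truth.coupling == {(0, 1): 0.5}

    def test_stationary_and_trophallaxis_bouts_are_subthreshold(self):
        p = ColonySimParams(n_bees=6, n_frames=2000, stationary_prob=0.05,
                            trophallaxis_rate=20.0, dropout_prob=0.0, seed=8)
        traj, truth = simulate_trajectories(p)
        ev = truth.trophallaxis_events
        assert len(ev) > 0
        piv_x = traj.frames.pivot_table(index="frame", columns="bee_id", values="x_mm")
        piv_y = traj.frames.pivot_table(index="frame", columns="bee_id", values="y_mm")
        for row in ev.itertuples(index=False):
            for bee in (row.bee_a, row.bee_b):
                # skip the entry frame (the approach step may be large)
                fr = slice(row.start_frame + 1, row.end_frame + 1)
                steps = np.hypot(piv_x[bee].diff()[fr], piv_y[bee].diff()[fr])
                assert (steps.dropna() < 4.9).all()
            # partners stay within the trophallaxis detector's reach
            d = np.hypot(piv_x[row.bee_a][fr] - piv_x[row.bee_b][fr],
                         piv_y[row.bee_a][fr] - piv_y[row.bee_b][fr])
            assert (d.dropna() <= 7.4 + 1e-6).all()


class TestSimulateCoupledPair:
    def test_deterministic_and_independent_at_zero(self):
        a1 = simulate_coupled_pair(500, c=0.0, seed=5)
        a2 = simulate_coupled_pair(500, c=0.0, seed=5)
        np.testing.assert_array_equal(a1[0], a2[0])
        L, F = simulate_coupled_pair(10_000, c=0.0, seed=1)
        dl, df = np.diff(L[:, 0]), np.diff(F[:, 0])
        assert abs(np.corrcoef(dl[:-1], df[1:])[0, 1]) < 0.05

    def test_coupling_strength_raises_lagged_correlation(self):
        L, F = simulate_coupled_pair(10_000, c=0.5, seed=1)
        dl, df = np.diff(L[:, 0]), np.diff(F[:, 0])
        assert np.corrcoef(dl[:-1], df[1:])[0, 1] > 0.3

    def test_invalid_coupling(self):
        with pytest.raises(ValueError):
            simulate_coupled_pair(100, c=1.0)


class TestSimulateVar:
    def test_white_noise_covariance(self):
        x = simulate_var([np.zeros((2, 2))], np.eye(2), 20_000, seed=0)
        np.testing.assert_allclose(np.cov(x.T), np.eye(2), atol=0.05)

    def test_stationary_covariance_matches_lyapunov_fixed_point(self):
        A = np.array([[0.5, 0.0], [0.3, 0.5]])
        x = simulate_var([A], np.eye(2), 50_000, seed=13)
        # independent oracle: fixed-point iteration of S = A S A' + I
        S = np.eye(2)
        for _ in range(500):
            S = A @ S @ A.T + np.eye(2)
        np.testing.assert_allclose(np.cov(x.T), S, atol=0.05)

    def test_unstable_coefficients_rejected(self):
        with pytest.raises(ValueError, match="unstable"):
            simulate_var([np.array([[1.1, 0.0], [0.0, 0.5]])], np.eye(2), 100)

    def test_non_psd_covariance_rejected(self):
        with pytest.raises(ValueError, match="semidefinite"):
            simulate_var([np.zeros((2, 2))], np.array([[1.0, 2.0], [2.0, 1.0]]), 100)


class TestSimulateTripLog:
    def test_foragers_satisfy_every_clause(self):
        trips, truth = simulate_trip_log(10, 4, forager_ids={0, 3}, seed=0)
        flags = classify_forager(trips, bee_ids=range(10)).set_index("bee_id")
        for bee in (0, 3):
            assert flags.loc[bee, "forager"]
            assert flags.loc[bee, "n_trips"] >= 6
            assert flags.loc[bee, "n_qualifying_days"] >= 2
            assert flags.loc[bee, "peak_fraction"] >= 0.25

    def test_non_foragers_violate_a_recorded_clause(self):
        trips, truth = simulate_trip_log(12, 4, forager_ids={0}, seed=1)
        flags = classify_forager(trips, bee_ids=range(12)).set_index("bee_id")
        for bee in range(1, 12):
            assert not flags.loc[bee, "forager"]
            clause = truth.forager_clause_violations[bee]
            if clause == "total":
                assert flags.loc[bee, "n_trips"] < 6
            elif clause == "days":
                assert flags.loc[bee, "n_qualifying_days"] < 2
            elif clause == "peak":
                assert flags.loc[bee, "peak_fraction"] < 0.25
            elif clause == "zero":
                assert flags.loc[bee, "n_trips"] == 0

    def test_zero_days_empty_table(self):
        trips, _ = simulate_trip_log(5, 0, forager_ids=set(), seed=0)
        assert trips.empty


class TestSimulateAssay:
    def test_labels_produce_expected_durations(self):
        labels = {0: "guard", 1: "nurse", 2: "non_responder", 3: "baseline", 4: "generalist"}
        assays = simulate_assay(5, labels, seed=0)

        def dur(bee, behaviors):
            rows = assays[(assays["bee_id"] == bee) & assays["behavior"].isin(behaviors)]
            return rows["total_duration_s"].sum()

        assert dur(0, ["bite", "sting"]) >= 20 and dur(0, ["feed"]) < 20
        assert dur(1, ["feed"]) >= 20 and dur(1, ["bite", "sting"]) < 20
        assert dur(2, ["bite", "sting", "feed", "fan", "wax", "vibrate"]) == 0
        assert 0 < dur(3, ["bite", "sting"]) < 20
        assert dur(3, ["fan", "wax", "vibrate"]) > 0
        assert dur(4, ["bite", "sting"]) >= 20 and dur(4, ["feed"]) >= 20

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown label"):
            simulate_assay(1, {0: "queen"}, seed=0)


class TestSimulateGenotypes:
    def test_truth_matches_vectorized_score(self):
        effects = np.random.default_rng(0).normal(0, 1, 30)
        dosages, truth = simulate_genotypes(25, 30, effects, seed=4)
        eff = {f"snp{i + 1:05d}": effects[i] for i in range(30)}
        scores = polygenic_score(dosages, eff)
        for bee, expected in truth.prs.items():
            assert scores.iloc[bee] == pytest.approx(expected, abs=1e-12)

    def test_zero_effects_zero_scores(self):
        _, truth = simulate_genotypes(10, 5, np.zeros(5), seed=1)
        assert all(v == 0.0 for v in truth.prs.values())

    def test_dosages_in_range_and_deterministic(self):
        d1, _ = simulate_genotypes(10, 20, np.zeros(20), seed=9)
        d2, _ = simulate_genotypes(10, 20, np.zeros(20), seed=9)
        pd.testing.assert_frame_equal(d1, d2)
        vals = d1.drop(columns="bee_id").to_numpy()
        assert set(np.unique(vals)) <= {0, 1, 2}
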