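"""Ground-truthed synthetic colony generator.

Emulates the inputs of the tracking pipeline: ~1 Hz barcode detections of
individually identified bees (with dropout and stationary bouts), pairwise
directional movement coupling of controllable strength, trophallaxis
episodes, hive-entrance trips, laboratory assay observations, and biallelic
SNP dosages.

The movement model is an AR(1)-velocity random walk: each bee's per-frame
displacement follows d(t) = phi * d(t-1) + eta(t) independently per axis
(plus a weak pull toward the cluster center, emulating comb clustering), and
a coupled follower additionally receives c times the leader's realized
displacement at t-1.  On displacements this is exactly a bivariate VAR,
which makes the downstream influence estimation identifiable against ground
truth.  Positions reflect at the hive walls; stationary and trophallaxis
bouts emit sub-threshold jitter (< 4.9 mm, < 60 deg per frame) so the
kinematic stationarity rule can be exercised.

Proximal interactions in real colonies are co-walking/following episodes:
two bees moving at walking speed while staying within a couple of
centimetres of each other.  Independent random walkers essentially never do
this (their relative position diffuses as fast as they walk), so the
generator injects explicit co-walk episodes — a shared smooth flow at
supra-threshold speed plus small individual jitter and a weak mutual
spring — scheduled like the trophallaxis episodes and logged in the ground
truth.  These episodes are what the proximity stage should recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .trajectories import TrajectoryTable
from .behavior import BEHAVIOR_LABELS

# Generator constants (units: mm, degrees, frames).  phi and the innovation
# scale put typical walking displacements around 8-12 mm/frame at 1 frame/s,
# i.e. an actively walking bee, comfortably above the 4.9 mm stationarity
# threshold; jitter amplitudes sit well below both thresholds.
AR_COEF = 0.5
INNOVATION_SD_MM = 6.0
JITTER_MM = 1.0
JITTER_DEG = 10.0
STATIONARY_MEAN_FRAMES = 30
TROPH_PAIR_GAP_MM = 5.0          # within the detector's 1.7-7.4 mm geometry
TROPH_MEAN_DURATION_S = 20.0

# co-walk episode parameters: shared flow fast enough that both bees stay
# above the 4.9 mm stationarity threshold, individual jitter slow enough that
# the pair stays inside the 20 mm proximity radius
COWALK_SPEED_MM = 8.0
COWALK_SPEED_SD = 1.5
COWALK_TURN_SD_RAD = 0.35
COWALK_JITTER_SD = 1.0
COWALK_GAP_MM = 10.0
COWALK_MEAN_DURATION_S = 90.0
COWALK_MIN_DURATION_S = 40.0


@dataclass
class ColonySimParams:
    """Conditions of a simulated recording.

    ``coupling`` maps ordered (leader, follower) bee-id pairs to the
    dimensionless coupling coefficient c (|c| < 1) with which the follower's
    velocity tracks the leader's previous displacement.
    """

    n_bees: int
    n_frames: int
    fs: float = 1.0
    hive_width_mm: float = 448.0
    hive_height_mm: float = 232.0
    coupling: dict = field(default_factory=dict)
    dropout_prob: float = 0.02
    stationary_prob: float = 0.01      # per-frame probability of entering a bout
    trophallaxis_rate: float = 1.0     # expected raw events per bee-hour
    cowalk_rate: float = 8.0           # expected co-walk episodes per bee-hour
    cohesion: float = 0.02             # per-frame pull toward the cluster center
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bees < 2:
            raise ValueError("n_bees must be at least 2")
        if self.n_frames < 1:
            raise ValueError("n_frames must be positive")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.hive_width_mm <= 0 or self.hive_height_mm <= 0:
            raise ValueError("hive dimensions must be positive")
        if not (0 <= self.dropout_prob < 1):
            raise ValueError("dropout_prob must be in [0, 1)")
        for (leader, follower), c in self.coupling.items():
            if abs(c) >= 1:
                raise ValueError(f"|coupling| must be < 1, got {c} for {(leader, follower)}")
            for bee in (leader, follower):
                if not (0 <= bee < self.n_bees):
                    raise ValueError(f"coupling references unknown bee id {bee}")


@dataclass
class GroundTruth:
    """What the generator actually injected, for validating the pipeline."""

    coupling: dict = field(default_factory=dict)
    labels: dict = field(default_factory=dict)            # bee -> behavior label
    prs: dict = field(default_factory=dict)               # bee -> true polygenic score
    trophallaxis_events: pd.DataFrame | None = None       # injected episodes
    cowalk_events: pd.DataFrame | None = None             # injected co-walk episodes
    trips: pd.DataFrame | None = None                     # injected trip log
    forager_clause_violations: dict = field(default_factory=dict)


def simulate_trajectories(params: ColonySimParams) -> tuple[TrajectoryTable, GroundTruth]:
    """Simulate the per-frame detection table of a colony.

    Deterministic given ``params.seed``.  Returns the trajectory table and a
    :class:`GroundTruth` carrying the coupling matrix and the injected
    trophallaxis and co-walk episode logs.
    """
    rng = np.random.default_rng(params.seed)
    n, T = params.n_bees, params.n_frames
    W, H = params.hive_width_mm, params.hive_height_mm
    margin = JITTER_MM + 0.5
    center = np.array([W / 2.0, H / 2.0])

    pos = np.column_stack([rng.uniform(margin, W - margin, n),
                           rng.uniform(margin, H - margin, n)])
    heading = rng.uniform(0.0, 360.0, n)
    d_state = np.zeros((n, 2))          # AR displacement state
    last_disp = np.zeros((n, 2))        # realized displacement at t-1
    u_state = np.zeros((n, 2))          # individual jitter during co-walks
    stationary_left = np.zeros(n, dtype=int)
    troph_left = np.zeros(n, dtype=int)
    cowalking = np.zeros(n, dtype=bool)
    anchor = pos.copy()

    # schedule trophallaxis and co-walk episodes ahead of time
    hours = T / (params.fs * 3600.0)
    n_events = rng.poisson(params.trophallaxis_rate * params.n_bees * hours)
    schedule: dict[int, list[tuple[int, int, int]]] = {}
    for _ in range(n_events):
        a, b = rng.choice(n, size=2, replace=False)
        dur_s = np.clip(rng.exponential(TROPH_MEAN_DURATION_S), 1.0, 240.0)
        dur = max(int(round(dur_s * params.fs)), 1)
        start = int(rng.integers(0, max(T - dur, 1)))
        schedule.setdefault(start, []).append((int(a), int(b), dur))
    n_cowalks = rng.poisson(params.cowalk_rate * params.n_bees * hours / 2.0)
    cowalk_schedule: dict[int, list[tuple[int, int, int]]] = {}
    cowalk_count = np.zeros(n, dtype=int)
    for _ in range(n_cowalks):
        # balanced partner draw: least-scheduled bee initiates, partner random,
        # so episode coverage spreads over the whole colony
        least = np.flatnonzero(cowalk_count == cowalk_count.min())
        a = int(rng.choice(least))
        b = int(rng.choice([i for i in range(n) if i != a]))
        cowalk_count[a] += 1
        cowalk_count[b] += 1
        dur_s = np.clip(rng.exponential(COWALK_MEAN_DURATION_S),
                        COWALK_MIN_DURATION_S, 240.0)
        dur = max(int(round(dur_s * params.fs)), 1)
        start = int(rng.integers(1, max(T - dur, 2)))
        cowalk_schedule.setdefault(start, []).append((int(a), int(b), dur))
    event_log: list[tuple[int, int, int, int]] = []
    cowalk_log: list[tuple[int, int, int, int]] = []
    episodes: list[dict] = []           # active co-walk episodes

    X = np.empty((n, T))
    Y = np.empty((n, T))
    O = np.empty((n, T))
    X[:, 0], Y[:, 0], O[:, 0] = pos[:, 0], pos[:, 1], heading

    couplings = [(int(l), int(f), float(c)) for (l, f), c in params.coupling.items()]

    for t in range(1, T):
        # trophallaxis episode starts (only between currently free bees)
        for a, b, dur in schedule.get(t, ()):
            if troph_left[a] == 0 and troph_left[b] == 0 and not cowalking[a] and not cowalking[b]:
                troph_left[a] = troph_left[b] = dur
                mid = (pos[a] + pos[b]) / 2.0
                offset = rng.normal(size=2)
                offset *= (TROPH_PAIR_GAP_MM / 2.0) / np.linalg.norm(offset)
                anchor[a] = np.clip(mid + offset, margin, [W - margin, H - margin])
                anchor[b] = np.clip(mid - offset, margin, [W - margin, H - margin])
                event_log.append((a, b, t, t + dur - 1))

        # co-walk episode starts: partner b joins a, then both follow a shared flow
        for a, b, dur in cowalk_schedule.get(t, ()):
            busy = (troph_left[a] > 0 or troph_left[b] > 0 or cowalking[a]
                    or cowalking[b] or stationary_left[a] > 0 or stationary_left[b] > 0)
            if busy:
                continue
            cowalking[a] = cowalking[b] = True
            offset = rng.normal(size=2)
            offset *= COWALK_GAP_MM / np.linalg.norm(offset)
            pos[b] = np.clip(pos[a] + offset, margin, [W - margin, H - margin])
            episodes.append({"a": a, "b": b, "left": dur,
                             "theta": rng.uniform(0.0, 2 * np.pi)})
            u_state[[a, b]] = 0.0
            cowalk_log.append((a, b, t, t + dur - 1))

        # stationary bout entries
        free = (stationary_left == 0) & (troph_left == 0) & ~cowalking
        entering = free & (rng.random(n) < params.stationary_prob)
        if entering.any():
            stationary_left[entering] = rng.geometric(
                1.0 / STATIONARY_MEAN_FRAMES, entering.sum())
            anchor[entering] = pos[entering]

        eta = rng.normal(0.0, INNOVATION_SD_MM, (n, 2))
        d_state = AR_COEF * d_state + eta + params.cohesion * (center - pos)

        # co-walk dynamics override the free walk: shared flow + individual jitter
        for ep in episodes:
            a, b = ep["a"], ep["b"]
            mid = (pos[a] + pos[b]) / 2.0
            # steer the flow back toward the hive center near walls
            ahead = mid + 10.0 * COWALK_SPEED_MM * np.array(
                [np.cos(ep["theta"]), np.sin(ep["theta"])])
            if not (margin < ahead[0] < W - margin and margin < ahead[1] < H - margin):
                to_center = center - mid
                ep["theta"] = np.arctan2(to_center[1], to_center[0]) + rng.normal(0.0, 0.3)
            ep["theta"] += rng.normal(0.0, COWALK_TURN_SD_RAD)
            speed = float(np.clip(COWALK_SPEED_MM + rng.normal(0.0, COWALK_SPEED_SD),
                                  6.0, 12.0))
            g = speed * np.array([np.cos(ep["theta"]), np.sin(ep["theta"])])
            for bee, mate in ((a, b), (b, a)):
                u = 0.5 * u_state[bee] + rng.normal(0.0, COWALK_JITTER_SD, 2)
                gap = pos[mate] - pos[bee]
                dist = np.linalg.norm(gap)
                if dist > COWALK_GAP_MM:   # weak spring keeps the pair together
                    u = u + 0.2 * (dist - COWALK_GAP_MM) * gap / dist
                u_state[bee] = u
                d_state[bee] = g + u

        for leader, follower, c in couplings:
            d_state[follower] += c * last_disp[leader]

        moving = (stationary_left == 0) & (troph_left == 0)
        new_pos = pos.copy()
        new_pos[moving] += d_state[moving]
        jittering = ~moving
        if jittering.any():
            new_pos[jittering] = anchor[jittering] + rng.uniform(
                -JITTER_MM, JITTER_MM, (int(jittering.sum()), 2))
            heading[jittering] = (heading[jittering] + rng.uniform(
                -JITTER_DEG, JITTER_DEG, int(jittering.sum()))) % 360.0

        # reflect at hive walls, flipping the AR state on the bounced axis
        for axis, bound in ((0, W), (1, H)):
            under = new_pos[:, axis] < 0
            new_pos[under, axis] = -new_pos[under, axis]
            d_state[under, axis] = -d_state[under, axis]
            over = new_pos[:, axis] > bound
            new_pos[over, axis] = 2 * bound - new_pos[over, axis]
            d_state[over, axis] = -d_state[over, axis]
        np.clip(new_pos[:, 0], 0.0, W, out=new_pos[:, 0])
        np.clip(new_pos[:, 1], 0.0, H, out=new_pos[:, 1])

        disp = new_pos - pos
        head_move = moving & (np.linalg.norm(disp, axis=1) > 1e-9)
        heading[head_move] = np.degrees(
            np.arctan2(disp[head_move, 1], disp[head_move, 0])) % 360.0

        last_disp = disp
        pos = new_pos
        stationary_left[stationary_left > 0] -= 1
        ending = troph_left == 1
        troph_left[troph_left > 0] -= 1
        d_state[ending] = 0.0
        for ep in list(episodes):
            ep["left"] -= 1
            if ep["left"] <= 0:
                cowalking[[ep["a"], ep["b"]]] = False
                episodes.remove(ep)

        X[:, t], Y[:, t], O[:, t] = pos[:, 0], pos[:, 1], heading

    detected = rng.random((n, T)) >= params.dropout_prob
    bee_idx, frame_idx = np.nonzero(detected)
    df = pd.DataFrame({
        "bee_id": bee_idx,
        "frame": frame_idx,
        "x_mm": X[bee_idx, frame_idx],
        "y_mm": Y[bee_idx, frame_idx],
        "orientation_deg": O[bee_idx, frame_idx],
    })
    traj = TrajectoryTable(df, fs=params.fs, hive_width_mm=W, hive_height_mm=H)
    def _pair_table(log: list) -> pd.DataFrame:
        ev = pd.DataFrame(log, columns=["bee_a", "bee_b", "start_frame", "end_frame"])
        if not ev.empty:
            swap = ev["bee_a"] > ev["bee_b"]
            ev.loc[swap, ["bee_a", "bee_b"]] = ev.loc[swap, ["bee_b", "bee_a"]].to_numpy()
        return ev

    truth = GroundTruth(coupling=dict(params.coupling),
                        trophallaxis_events=_pair_table(event_log),
                        cowalk_events=_pair_table(cowalk_log))
    return traj, truth


def simulate_coupled_pair(n_frames: int, c: float = 0.0, seed: int = 0,
                          fs: float = 1.0, ar_coef: float = AR_COEF,
                          innovation_sd: float = INNOVATION_SD_MM,
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Leader/follower position series from the colony movement model, wall-free.

    Returns (leader_xy, follower_xy), each (n_frames, 2).  With c = 0 the two
    bees are independent; with c > 0 the follower's velocity adds c times the
    leader's displacement at the previous frame.
    """
    if abs(c) >= 1:
        raise ValueError("|c| must be < 1")
    rng = np.random.default_rng(seed)
    d = np.zeros((2, 2))
    pos = np.zeros((2, 2))
    out = np.empty((n_frames, 2, 2))
    out[0] = pos
    for t in range(1, n_frames):
        eta = rng.normal(0.0, innovation_sd, (2, 2))
        new_d = ar_coef * d + eta
        new_d[1] += c * d[0]           # follower tracks leader's last displacement
        d = new_d
        pos = pos + d
        out[t] = pos
    return out[:, 0, :].copy(), out[:, 1, :].copy()


def simulate_var(coefficients, innovation_cov, n: int, seed: int = 0,
                 burn: int = 500) -> np.ndarray:
    """Exact samples from a stable VAR(p) process.

    Parameters
    ----------
    coefficients : sequence of (k, k) arrays
        A_1..A_p; the companion-matrix spectral radius must be < 1.
    innovation_cov : (k, k) symmetric PSD array
    n : number of samples returned (after burn-in)
    """
    A = [np.asarray(a, dtype=float) for a in coefficients]
    k = A[0].shape[0]
    p = len(A)
    if any(a.shape != (k, k) for a in A):
        raise ValueError("coefficient matrices must share a square shape")
    top = np.hstack(A)
    comp = top if p == 1 else np.vstack(
        [top, np.hstack([np.eye(k * (p - 1)), np.zeros((k * (p - 1), k))])])
    radius = np.max(np.abs(np.linalg.eigvals(comp)))
    if radius >= 1.0:
        raise ValueError(f"unstable VAR: companion spectral radius {radius:.3f} >= 1")
    S = np.asarray(innovation_cov, dtype=float)
    if S.shape != (k, k) or not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("innovation_cov must be symmetric (k, k)")
    evals, evecs = np.linalg.eigh(S)
    if np.min(evals) < -1e-10:
        raise ValueError("innovation_cov must be positive semidefinite")
    chol = evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None)))

    rng = np.random.default_rng(seed)
    total = n + burn
    x = np.zeros((total + p, k))
    eps = rng.standard_normal((total, k)) @ chol.T
    for t in range(p, total + p):
        acc = eps[t - p]
        for m in range(1, p + 1):
            acc = acc + A[m - 1] @ x[t - m]
        x[t] = acc
    return x[p + burn:]


PEAK_START = "10:00"
PEAK_END = "15:00"
_BASE_DATE = date(2023, 6, 1)


def _trip_time(rng: np.random.Generator, in_peak: bool) -> str:
    if in_peak:
        minute = int(rng.integers(10 * 60, 15 * 60))
    else:
        minute = int(rng.choice(np.concatenate([np.arange(7 * 60, 10 * 60),
                                                np.arange(15 * 60 + 1, 19 * 60)])))
    return f"{minute // 60:02d}:{minute % 60:02d}:00"


def simulate_trip_log(n_bees: int, n_days: int, forager_ids,
                      seed: int = 0, zero_trip_ids=None) -> tuple[pd.DataFrame, GroundTruth]:
    """Entrance-monitor trip log with foragers satisfying the forager rule.

    Designated foragers get at least two days with >= 4 trips, >= 6 trips in
    total, and >= 25% of trips during peak hours (10:00-15:00).  Other bees
    receive patterns violating at least one clause; bees in ``zero_trip_ids``
    take no trips at all.  The ground truth records which clause each
    non-forager violates.
    """
    forager_ids = set(forager_ids)
    zero_trip_ids = set(zero_trip_ids or ())
    if not forager_ids <= set(range(n_bees)):
        raise ValueError("forager_ids contains unknown bee ids")
    rng = np.random.default_rng(seed)
    rows: list[tuple[int, str, str]] = []
    violations: dict[int, str] = {}
    dates = [(_BASE_DATE + timedelta(days=d)).isoformat() for d in range(n_days)]

    def add_trips(bee: int, day: str, k: int, peak_k: int) -> None:
        for i in range(k):
            rows.append((bee, day, _trip_time(rng, in_peak=i < peak_k)))

    for bee in range(n_bees):
        if n_days == 0:
            if bee not in forager_ids:
                violations[bee] = "total" if bee not in zero_trip_ids else "zero"
            continue
        if bee in forager_ids:
            if n_days < 2:
                raise ValueError("foragers need at least 2 days of recording")
            days = rng.choice(n_days, size=2, replace=False)
            total_peak_needed = 0
            for d in days:
                k = int(rng.integers(4, 9))
                peak_k = max(int(np.ceil(0.3 * k)), 1)
                add_trips(bee, dates[d], k, peak_k)
        elif bee in zero_trip_ids:
            violations[bee] = "zero"
        else:
            mode = rng.choice(["total", "days", "peak"])
            violations[bee] = str(mode)
            if mode == "total":
                # fewer than 6 trips overall
                k = int(rng.integers(1, 6))
                for _ in range(k):
                    d = int(rng.integers(0, n_days))
                    rows.append((bee, dates[d], _trip_time(rng, in_peak=bool(rng.random() < 0.5))))
            elif mode == "days" and n_days >= 2:
                # >= 6 total but only one day reaches 4 trips
                add_trips(bee, dates[0], 5, 3)
                add_trips(bee, dates[1], 2, 1)
            else:
                violations[bee] = "peak"
                if n_days >= 2:
                    # counts qualify but all trips outside peak hours
                    add_trips(bee, dates[0], 4, 0)
                    add_trips(bee, dates[1], 4, 0)
    trips = pd.DataFrame(rows, columns=["bee_id", "date", "time"])
    truth = GroundTruth(trips=trips, forager_clause_violations=violations)
    return trips, truth


_QUALIFYING = {"guard": "aggression", "nurse": "care"}


def simulate_assay(n_bees: int, label_assignment, seed: int = 0) -> pd.DataFrame:
    """Dish-assay observation table consistent with an intended label per bee.

    ``label_assignment`` maps bee id -> label from the behavior vocabulary.
    Guards get >= 20 s of biting/stinging, nurses >= 20 s larval feeding,
    non-responders zero everywhere, baselines sub-threshold responses plus a
    fanning/wax/vibration record, generalists two qualifying behaviors
    (aggression and care; forager-including generalists are composed by the
    caller via the trip log).
    """
    rng = np.random.default_rng(seed)
    if not isinstance(label_assignment, dict):
        label_assignment = dict(enumerate(label_assignment))
    rows: list[tuple[int, str, str, float]] = []

    def agg(bee: int, total: float) -> None:
        bite = total * rng.uniform(0.4, 0.8)
        rows.append((bee, "intruder", "bite", round(bite, 1)))
        rows.append((bee, "intruder", "sting", round(total - bite, 1)))

    def care(bee: int, total: float) -> None:
        rows.append((bee, "larva", "feed", round(total, 1)))

    for bee, label in label_assignment.items():
        if label not in BEHAVIOR_LABELS:
            raise ValueError(f"unknown label {label!r} for bee {bee}")
        if label == "guard":
            agg(bee, float(rng.uniform(22, 60)))
            care(bee, float(rng.uniform(0, 8)))
        elif label == "nurse":
            care(bee, float(rng.uniform(22, 60)))
            agg(bee, float(rng.uniform(0, 8)))
        elif label == "generalist":
            agg(bee, float(rng.uniform(22, 60)))
            care(bee, float(rng.uniform(22, 60)))
        elif label == "forager":
            agg(bee, float(rng.uniform(0, 8)))
            care(bee, float(rng.uniform(0, 8)))
        elif label == "non_responder":
            rows.append((bee, "intruder", "bite", 0.0))
            rows.append((bee, "larva", "feed", 0.0))
        elif label == "baseline":
            agg(bee, float(rng.uniform(2, 15)))
            care(bee, float(rng.uniform(0, 10)))
            other = str(rng.choice(["fan", "wax", "vibrate"]))
            rows.append((bee, "larva", other, round(float(rng.uniform(5, 30)), 1)))
    return pd.DataFrame(rows, columns=["bee_id", "assay", "behavior", "total_duration_s"])


def simulate_genotypes(n_bees: int, n_snps: int, effect_sizes,
                       maf_range: tuple[float, float] = (0.05, 0.5),
                       seed: int = 0) -> tuple[pd.DataFrame, GroundTruth]:
    """Biallelic SNP dosage matrix plus ground-truth polygenic scores.

    Dosages (counts of the alternative allele) are drawn Binomial(2, maf)
    independently per SNP with maf uniform in ``maf_range``.  The true score
    is the dosage-by-effect inner product computed by an explicit double loop,
    independent of any vectorized implementation it may be checked against.
    """
    effects = np.asarray(effect_sizes, dtype=float)
    if len(effects) != n_snps:
        raise ValueError("effect_sizes must have length n_snps")
    lo, hi = maf_range
    if not (0 < lo <= hi < 0.5 or (0 < lo <= hi <= 0.5)):
        raise ValueError("maf_range must lie in (0, 0.5]")
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(lo, hi, n_snps)
    dosages = rng.binomial(2, mafs, size=(n_bees, n_snps))
    snp_ids = [f"snp{i + 1:05d}" for i in range(n_snps)]
    df = pd.DataFrame(dosages, columns=snp_ids)
    df.insert(0, "bee_id", np.arange(n_bees))
    prs = {}
    for b in range(n_bees):             # deliberate double loop: the oracle
        acc = 0.0
        for s in range(n_snps):
            acc += float(dosages[b, s]) * float(effects[s])
        prs[b] = acc
    return df, GroundTruth(prs=prs)
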