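"""Moving-circles paradigm simulation for a yoked stressor-controllability study.

Two circles move smoothly on a screen; when they collide a mild electric
stressor is delivered.  The motion is organised in approach/retreat segments
of 2-9 s, with the total approach time equated to the total retreat time.
Each 3-min block contains 0-3 collisions (25 over a default 6-run session)
and deliberate "near misses" where the circles come within 1.5 circle
diameters edge-to-edge and retreat (7 per run on average).

The controllable member of each yoked pair terminates the stressor by
pressing a button that turns a virtual wheel by 30 degrees per press; the
number of presses required to terminate starts at one and escalates by one
after each successful termination, capped at 12.  The uncontrollable member
experiences exactly the same stressor durations and sees the wheel rotate
with the yoked member's press timing, but with random rotation amounts.

Distances are expressed edge-to-edge in units of one circle diameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from ._util import read_tsv, rng_for, write_tsv

__all__ = [
    "DEFAULT_DURATION_SCHEDULE",
    "MotionConfig",
    "WheelConfig",
    "CircleSession",
    "StressorTrial",
    "PairBehavior",
    "generate_trajectory",
    "classify_proximity",
    "detect_near_misses",
    "simulate_wheel_trials",
    "write_events",
    "read_events",
]

# Stressor (shock + sound) durations in seconds for a default 25-collision
# session: sampled once from a lognormal fit to the printed summary
# statistics and frozen.  Sorted ascending, i.e. assigned chronologically,
# mirroring the escalating press requirement which lengthened stressors as
# the session progressed.  Median 1.37 s, range 0.16-4.27 s, bulk in 0.5-3 s.
DEFAULT_DURATION_SCHEDULE: tuple[float, ...] = (
    0.16, 0.31, 0.47, 0.58, 0.66, 0.79, 0.88, 0.97, 1.08, 1.16, 1.24, 1.31,
    1.37, 1.46, 1.58, 1.66, 1.79, 1.94, 2.12, 2.33, 2.51, 2.74, 3.02, 3.55,
    4.27,
)

# frame segment-label codes
APPROACH, RETREAT, STRESSOR = 0, 1, 2
LABEL_NAMES = {APPROACH: "approach", RETREAT: "retreat", STRESSOR: "stressor"}


class ConstraintError(ValueError):
    """Raised when a paradigm configuration is internally infeasible."""


class ScheduleError(ValueError):
    """Raised when the stressor-duration schedule cannot cover the session."""


@dataclass(frozen=True)
class MotionConfig:
    """Parameters of the circle-motion generator.

    Defaults reproduce the full experimental session: 6 runs of two 3-min
    blocks, 25 collisions total with 0-3 per block, segments of 2-9 s, and
    7 near-misses per run.
    """

    n_runs: int = 6
    blocks_per_run: int = 2
    block_duration: float = 180.0
    inter_block_off: float = 30.0
    run_lead_blank: float = 15.0
    run_tail_blank: float = 15.0
    frame_rate: float = 20.0
    segment_duration_range: tuple[float, float] = (2.0, 9.0)
    near_miss_edge_threshold: float = 1.5
    total_collisions: int = 25
    collisions_per_block_range: tuple[int, int] = (0, 3)
    near_misses_per_run_mean: float = 7.0
    proximity_near_fraction: float = 1.0 / 3.0
    max_distance: float = 10.0
    motion_wiggle: float = 18.0
    seed: int = 0

    @property
    def n_blocks(self) -> int:
        return self.n_runs * self.blocks_per_run

    @property
    def run_duration(self) -> float:
        """Nominal wall-clock duration of one run in seconds."""
        return (
            self.run_lead_blank
            + self.blocks_per_run * self.block_duration
            + (self.blocks_per_run - 1) * self.inter_block_off
            + self.run_tail_blank
        )

    def block_start(self, run: int, block: int) -> float:
        return (
            run * self.run_duration
            + self.run_lead_blank
            + block * (self.block_duration + self.inter_block_off)
        )

    def validate(self) -> None:
        lo, hi = self.collisions_per_block_range
        if not (0 <= lo <= hi):
            raise ConstraintError("collisions_per_block_range must satisfy 0 <= lo <= hi")
        if not (lo * self.n_blocks <= self.total_collisions <= hi * self.n_blocks):
            raise ConstraintError(
                f"total_collisions={self.total_collisions} cannot be split over "
                f"{self.n_blocks} blocks with per-block range {self.collisions_per_block_range}"
            )
        a, b = self.segment_duration_range
        if not (0 < a <= b):
            raise ConstraintError("segment_duration_range must be positive and ordered")
        if self.max_distance <= self.near_miss_edge_threshold:
            raise ConstraintError("max_distance must exceed the near-miss threshold")
        if self.frame_rate <= 0:
            raise ConstraintError("frame_rate must be positive")


@dataclass(frozen=True)
class WheelConfig:
    """Virtual-wheel escalation and yoking parameters."""

    degrees_per_press: float = 30.0
    required_presses_start: int = 1
    required_presses_cap: int = 12
    unctl_compliance: float = 0.76
    duration_schedule: tuple[float, ...] = DEFAULT_DURATION_SCHEDULE

    def required_presses(self, trial_index: int) -> int:
        """Presses required on 0-based successful trial ``trial_index``."""
        return min(self.required_presses_start + trial_index, self.required_presses_cap)


@dataclass
class CircleSession:
    """Frame-by-frame circle kinematics plus the event schedule of one session."""

    times: np.ndarray          # absolute session time (s) of each frame
    distance: np.ndarray       # edge-to-edge distance in circle diameters
    labels: np.ndarray         # APPROACH / RETREAT / STRESSOR per frame
    run_index: np.ndarray
    block_index: np.ndarray    # block within run
    collisions: list[tuple[float, float]]        # (onset s, duration s)
    near_misses: list[tuple[float, float]]       # (time s, min edge distance)
    max_distance: float
    frame_rate: float
    config: MotionConfig

    @property
    def n_collisions(self) -> int:
        return len(self.collisions)

    def near_misses_per_run(self) -> np.ndarray:
        counts = np.zeros(self.config.n_runs, dtype=int)
        run_dur = self.config.run_duration
        for t, _ in self.near_misses:
            counts[int(t // run_dur)] += 1
        return counts

    def approach_retreat_imbalance_frames(self) -> int:
        """|total approach frames - total retreat frames| for the session."""
        return abs(int(np.sum(self.labels == APPROACH)) - int(np.sum(self.labels == RETREAT)))


@dataclass
class StressorTrial:
    """One yoked stressor trial (identical timing for both pair members)."""

    onset: float
    duration: float
    required_presses: int
    ctl_press_times: np.ndarray
    unctl_press_times: np.ndarray     # subset of rotations answered
    rotation_times: np.ndarray        # identical to ctl presses (yoked)
    ctl_rotation_deg: np.ndarray      # constant 30-degree increments
    unctl_rotation_deg: np.ndarray    # random amounts, no progression


@dataclass
class PairBehavior:
    """Button-press and wheel records for one yoked participant pair."""

    trials: list[StressorTrial]
    compliance: float

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def press_total(self, member: str) -> int:
        if member == "CTL":
            return int(sum(len(t.ctl_press_times) for t in self.trials))
        if member == "UNCTL":
            return int(sum(len(t.unctl_press_times) for t in self.trials))
        raise KeyError(member)

    def press_counts(self, member: str) -> np.ndarray:
        if member == "CTL":
            return np.array([len(t.ctl_press_times) for t in self.trials])
        if member == "UNCTL":
            return np.array([len(t.unctl_press_times) for t in self.trials])
        raise KeyError(member)

    def onsets(self) -> np.ndarray:
        return np.array([t.onset for t in self.trials])

    def durations(self) -> np.ndarray:
        return np.array([t.duration for t in self.trials])


def _partition_frames(total: int, m: int, lo: int, hi: int, rng: np.random.Generator) -> np.ndarray:
    """Split ``total`` frames into ``m`` integer parts each within [lo, hi]."""
    if not (lo * m <= total <= hi * m):
        raise ConstraintError(
            f"cannot split {total} frames into {m} segments within [{lo}, {hi}]"
        )
    raw = rng.uniform(lo, hi, size=m)
    parts = np.floor(raw * total / raw.sum()).astype(int)
    parts = np.clip(parts, lo, hi)
    # repair the residual one frame at a time on segments with slack
    resid = total - int(parts.sum())
    step = 1 if resid > 0 else -1
    guard = 0
    while resid != 0:
        j = int(rng.integers(m))
        if lo <= parts[j] + step <= hi:
            parts[j] += step
            resid -= step
        guard += 1
        if guard > 100000:  # pragma: no cover - unreachable for feasible inputs
            raise ConstraintError("segment partition failed to converge")
    return parts


def _cosine_ramp(d0: float, d1: float, n: int) -> np.ndarray:
    """Smooth monotone path from d0 to d1 over n frames (endpoint included)."""
    phase = np.pi * np.arange(1, n + 1) / n
    return d0 + (d1 - d0) * 0.5 * (1.0 - np.cos(phase))


def _segment_path(
    d0: float,
    d1: float,
    n: int,
    rng: np.random.Generator,
    wiggle: float,
    near_threshold: float = 1.5,
    ceiling: float = 1e9,
) -> np.ndarray:
    """One approach or retreat segment with unpredictable internal motion.

    The backbone is a cosine ramp between the turning points.  Segments
    that visit the deep range near the floor use a power-sharpened profile
    so most of the distance change happens early and the final approach
    creeps in slowly.  A random sum of slow sinusoid harmonics (vanishing
    at both endpoints) is superimposed so the instantaneous radial speed
    frequently runs against the labeled direction, as in the experimental
    motion, which was smooth overall but locally unpredictable.  The
    fluctuation is soft-clipped between a floor just above the near-miss
    threshold and the ceiling, and is cosine-tapered to zero in time before
    the path enters the deep range, so that designated troughs are the only
    local minima at or below the near-miss threshold and collisions are
    approached monotonically.
    """
    floor = near_threshold + 0.005
    base_u = 0.5 * (1.0 - np.cos(np.pi * np.arange(1, n + 1) / n))
    lo = min(d0, d1)
    deep = lo < floor + 0.25
    if deep:
        g = 5.0  # creep through the deep range
        u = 1.0 - (1.0 - base_u) ** g if d1 < d0 else base_u ** g
    else:
        u = base_u
    base = d0 + (d1 - d0) * u
    if wiggle <= 0 or n < 8:
        return base
    tau = np.arange(1, n + 1) / n
    env = np.sin(np.pi * tau) ** 2
    wig = np.zeros(n)
    harmonics = (2, 3, 4)  # slow enough to survive hemodynamic smoothing
    for k in harmonics:
        wig += rng.uniform(-1.0, 1.0) * np.sin(k * np.pi * tau)
    amp = wiggle * abs(d1 - d0) * rng.uniform(0.7, 1.3) / np.sqrt(len(harmonics))
    amp = min(amp, 0.35 * n)
    w = wig * env * amp
    # heavy-tailed frame-scale kinks: sudden course changes of the circles
    # put broadband structure into the distance derivative
    w = w + env * np.clip(0.5 * rng.standard_t(2, size=n), -2.0, 2.0)
    # soft-clip between the floor and the ceiling: troughs stay the only
    # minima at or below the near-miss threshold.  The upward range also
    # shrinks with the distance to the floor so excursions die out before
    # the deep tail of a collision/near-miss approach.
    dn = np.maximum(base - floor, 1e-12)
    up = np.maximum(np.minimum(ceiling - base, 20.0 * dn), 1e-12)
    w = np.where(w < 0, -dn * np.tanh(-w / dn), up * np.tanh(w / up))
    w[base <= floor] = 0.0
    return base + w


def _split_collisions(config: MotionConfig, rng: np.random.Generator) -> np.ndarray:
    """Random per-block collision counts within range summing to the total."""
    lo, hi = config.collisions_per_block_range
    nb = config.n_blocks
    for _ in range(100000):
        counts = rng.multinomial(config.total_collisions, np.full(nb, 1.0 / nb))
        if counts.min() >= lo and counts.max() <= hi:
            return counts
    raise ConstraintError("could not place collisions within the per-block range")


def _near_miss_quota(config: MotionConfig, rng: np.random.Generator) -> np.ndarray:
    """Exact per-block near-miss counts: each run carries its configured mean."""
    per_run = config.near_misses_per_run_mean
    if abs(per_run - round(per_run)) > 1e-9 and config.blocks_per_run != 2:
        raise ConstraintError("near_misses_per_run_mean must be integral")
    quota = np.zeros(config.n_blocks, dtype=int)
    for r in range(config.n_runs):
        total = int(round(per_run))
        base = total // config.blocks_per_run
        extra = total - base * config.blocks_per_run
        counts = np.full(config.blocks_per_run, base)
        bump = rng.choice(config.blocks_per_run, size=extra, replace=False)
        counts[bump] += 1
        quota[r * config.blocks_per_run: (r + 1) * config.blocks_per_run] = counts
    return quota


def generate_trajectory(
    config: MotionConfig = MotionConfig(),
    duration_schedule: tuple[float, ...] | None = None,
) -> CircleSession:
    """Generate one full session of circle motion satisfying every constraint.

    The motion is built blockwise from approach/retreat cycles with
    cosine-ramped radial velocity.  Approach segment durations are mirrored
    (a shuffled copy) into retreat durations so the total approach and
    retreat times are exactly equated.  Collision troughs reach distance
    zero and hold it for the scheduled stressor duration; near-miss troughs
    bottom out within (0, 1.5] diameters; ordinary troughs stay above the
    near-miss threshold so the near-miss count is exact.
    """
    config.validate()
    if duration_schedule is None:
        duration_schedule = DEFAULT_DURATION_SCHEDULE
    if len(duration_schedule) < config.total_collisions:
        raise ScheduleError(
            f"duration schedule has {len(duration_schedule)} entries but the "
            f"session needs {config.total_collisions}"
        )
    rng = rng_for(config.seed, "trajectory")
    fr = config.frame_rate
    lo_f = int(np.ceil(config.segment_duration_range[0] * fr))
    hi_f = int(np.floor(config.segment_duration_range[1] * fr))
    block_frames_nominal = int(round(config.block_duration * fr))

    coll_counts = _split_collisions(config, rng)
    near_counts = _near_miss_quota(config, rng)

    times, dist, labels, run_ix, block_ix = [], [], [], [], []
    collisions: list[tuple[float, float]] = []
    near_misses: list[tuple[float, float]] = []
    coll_cursor = 0

    def build_block(nc: int, nn: int, durs: list[float]) -> dict:
        """Assemble one block; distances/labels plus block-relative events."""
        stress_frames = [max(1, int(round(d * fr))) for d in durs]
        avail = block_frames_nominal - sum(stress_frames)
        half = avail // 2  # approach total == retreat total exactly

        # number of cycles: mean segment duration lands above 6 s
        m_lo = int(np.ceil(half / hi_f))
        m_hi = max(m_lo, int(np.floor(half / (6.2 * fr))))
        m_min = max(m_lo, nc + nn + 1, m_hi - 1)
        m = int(rng.integers(m_min, max(m_hi, m_min) + 2))
        approach_f = _partition_frames(half, m, lo_f, hi_f, rng)
        retreat_f = rng.permutation(approach_f.copy())

        trough_kind = np.array(["coll"] * nc + ["near"] * nn + ["ord"] * (m - nc - nn))
        rng.shuffle(trough_kind)

        d_parts, l_parts = [], []
        colls, nears = [], []  # block-relative (frame offsets)
        peak = rng.uniform(0.65, 0.98) * config.max_distance
        cursor = 0
        k_coll = 0
        for i in range(m):
            kind = trough_kind[i]
            if kind == "coll":
                trough = 0.0
            elif kind == "near":
                trough = rng.uniform(0.6 * config.near_miss_edge_threshold, config.near_miss_edge_threshold)
            else:
                hi_tr = min(0.72 * config.max_distance, peak - 1.2)
                lo_tr = config.near_miss_edge_threshold + 0.7
                trough = rng.uniform(lo_tr, max(hi_tr, lo_tr + 0.3))
            na = int(approach_f[i])
            # a collision approach ends just above contact; the held-at-zero
            # frames that follow are the stressor itself
            target = 0.05 if kind == "coll" else trough
            d_parts.append(_segment_path(peak, target, na, rng, config.motion_wiggle, config.near_miss_edge_threshold, config.max_distance - 0.01))
            l_parts.append(np.full(na, APPROACH, dtype=np.int8))
            cursor += na

            if kind == "coll":
                nf = stress_frames[k_coll]
                colls.append((cursor, durs[k_coll]))
                d_parts.append(np.zeros(nf))
                l_parts.append(np.full(nf, STRESSOR, dtype=np.int8))
                cursor += nf
                k_coll += 1
            elif kind == "near":
                nears.append((cursor - 1, float(trough)))

            next_peak = rng.uniform(
                max(0.45 * config.max_distance, trough + 1.2), 0.98 * config.max_distance
            )
            nr = int(retreat_f[i])
            d_parts.append(_segment_path(trough, next_peak, nr, rng, config.motion_wiggle, config.near_miss_edge_threshold, config.max_distance - 0.01))
            l_parts.append(np.full(nr, RETREAT, dtype=np.int8))
            cursor += nr
            peak = next_peak

        return {
            "distance": np.concatenate(d_parts),
            "labels": np.concatenate(l_parts),
            "collisions": colls,
            "near_misses": nears,
        }

    def block_is_valid(blk, nn: int) -> bool:
        d, lab = blk["distance"], blk["labels"]
        nonstress = lab != STRESSOR
        if np.any(d[nonstress] <= 0.0):
            return False
        # near misses must be exactly the designated troughs (plateau-tolerant)
        hits = _subthreshold_minima(d, config.near_miss_edge_threshold)
        if len(hits) != nn:
            return False
        return all(
            any(abs(i - h) <= 3 for h in hits) for i, _ in blk["near_misses"]
        )

    for b in range(config.n_blocks):
        run, block = divmod(b, config.blocks_per_run)
        nc, nn = int(coll_counts[b]), int(near_counts[b])
        durs = [duration_schedule[coll_cursor + i] for i in range(nc)]
        for _attempt in range(200):
            blk = build_block(nc, nn, durs)
            if block_is_valid(blk, nn):
                break
        else:  # pragma: no cover - wiggle amplitudes make this unreachable
            raise ConstraintError("could not realize block constraints")

        t0 = config.block_start(run, block)
        n_block = blk["distance"].size
        times.append(t0 + np.arange(1, n_block + 1) / fr)
        dist.append(blk["distance"])
        labels.append(blk["labels"])
        run_ix.append(np.full(n_block, run, dtype=np.int16))
        block_ix.append(np.full(n_block, block, dtype=np.int16))
        for off, dur in blk["collisions"]:
            collisions.append((t0 + (off + 1) / fr, float(dur)))
        for off, dmin in blk["near_misses"]:
            near_misses.append((t0 + (off + 1) / fr, dmin))
        coll_cursor += nc

    session = CircleSession(
        times=np.concatenate(times),
        distance=np.concatenate(dist),
        labels=np.concatenate(labels),
        run_index=np.concatenate(run_ix),
        block_index=np.concatenate(block_ix),
        collisions=collisions,
        near_misses=near_misses,
        max_distance=config.max_distance,
        frame_rate=fr,
        config=config,
    )
    return session


def classify_proximity(session: CircleSession, near_fraction: float | None = None) -> np.ndarray:
    """Label every frame ``near`` (True) or ``far`` (False).

    Proximity is defined as 1 - d/d_max; a frame is "near" when proximity
    exceeds ``near_fraction`` (default 1/3), i.e. when the circles are
    closer than two-thirds of the maximum possible distance.  Collisions
    (d = 0) are always near; maximal separation is far.
    """
    if session.max_distance <= 0:
        raise ValueError("max_distance must be positive")
    if near_fraction is None:
        near_fraction = session.config.proximity_near_fraction
    proximity = 1.0 - session.distance / session.max_distance
    return proximity > near_fraction


def _subthreshold_minima(d: np.ndarray, thr: float, merge_frames: int = 20) -> list[int]:
    """Indices of local minima with 0 < d <= thr, merging plateau duplicates.

    Minima closer than ``merge_frames`` are treated as one event (the deep
    approach can flatten into a numerical plateau around the trough); the
    deepest frame of each group is kept.
    """
    interior = np.flatnonzero((d[1:-1] <= d[:-2]) & (d[1:-1] < d[2:])) + 1
    hits = [int(i) for i in interior if 0.0 < d[i] <= thr]
    merged: list[int] = []
    for i in hits:
        if merged and i - merged[-1] < merge_frames:
            if d[i] < d[merged[-1]]:
                merged[-1] = i
        else:
            merged.append(i)
    return merged


def detect_near_misses(session: CircleSession) -> list[tuple[float, float]]:
    """Recount near-misses from the frames alone (independent of bookkeeping).

    A near-miss is a local minimum of the distance trace with
    0 < d <= threshold, searched within each block.
    """
    thr = session.config.near_miss_edge_threshold
    out: list[tuple[float, float]] = []
    block_key = session.run_index.astype(int) * 1000 + session.block_index.astype(int)
    for key in np.unique(block_key):
        sel = block_key == key
        d = session.distance[sel]
        t = session.times[sel]
        for i in _subthreshold_minima(d, thr):
            out.append((float(t[i]), float(d[i])))
    return out


def simulate_wheel_trials(
    session: CircleSession,
    wheel: WheelConfig = WheelConfig(),
    seed: int = 0,
) -> PairBehavior:
    """Simulate yoked button-press behavior for both members of one pair.

    The controllable member terminates stressor ``k`` (0-based) with
    ``min(start + k, cap)`` presses placed inside the stressor window; the
    uncontrollable member sees rotations at exactly those times and answers
    each with probability ``unctl_compliance``, with random rotation amounts.
    """
    if session.n_collisions < 1:
        raise ValueError("session has no collisions to simulate trials for")
    if len(wheel.duration_schedule) < session.n_collisions:
        raise ScheduleError(
            f"duration schedule covers {len(wheel.duration_schedule)} trials, "
            f"session has {session.n_collisions}"
        )
    rng = rng_for(seed, "wheel")
    trials: list[StressorTrial] = []
    for k, (onset, duration) in enumerate(session.collisions):
        n_req = wheel.required_presses(k)
        # presses spread over the stressor window; the final press terminates
        jitter = rng.uniform(0.55, 1.0, size=n_req)
        frac = np.cumsum(jitter)
        frac = frac / frac[-1]
        press_t = onset + duration * frac
        answered = rng.random(n_req) < wheel.unctl_compliance
        trials.append(
            StressorTrial(
                onset=float(onset),
                duration=float(duration),
                required_presses=n_req,
                ctl_press_times=press_t,
                unctl_press_times=press_t[answered],
                rotation_times=press_t,
                ctl_rotation_deg=np.full(n_req, wheel.degrees_per_press),
                unctl_rotation_deg=rng.uniform(5.0, 60.0, size=n_req),
            )
        )
    return PairBehavior(trials=trials, compliance=wheel.unctl_compliance)


def write_events(
    behavior: PairBehavior,
    session: CircleSession,
    path,
    member: str = "CTL",
) -> pd.DataFrame:
    """Write a BIDS-style events table (TSV) for one pair member.

    One ``stressor`` row per trial with its press count, plus ``near_miss``
    rows (duration 0, empty press count).  Round-trips losslessly through
    :func:`read_events`.
    """
    counts = behavior.press_counts(member)
    rows = [
        {
            "onset": t.onset,
            "duration": t.duration,
            "trial_type": "stressor",
            "n_presses": float(c),
        }
        for t, c in zip(behavior.trials, counts)
    ]
    rows += [
        {"onset": t, "duration": 0.0, "trial_type": "near_miss", "n_presses": np.nan}
        for t, _ in session.near_misses
    ]
    df = pd.DataFrame(rows, columns=["onset", "duration", "trial_type", "n_presses"])
    df = df.sort_values("onset", kind="stable").reset_index(drop=True)
    write_tsv(df, path)
    return df


def read_events(path) -> pd.DataFrame:
    df = read_tsv(path)
    expected = ["onset", "duration", "trial_type", "n_presses"]
    if list(df.columns) != expected:
        raise ValueError(f"events file must have columns {expected}, got {list(df.columns)}")
    return df


def default_pair(seed: int = 0) -> tuple[CircleSession, PairBehavior]:
    """Convenience: default session plus yoked behavior for one pair."""
    session = generate_trajectory(replace(MotionConfig(), seed=seed))
    behavior = simulate_wheel_trials(session, WheelConfig(), seed=seed)
    return session, behavior
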