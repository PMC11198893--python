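"""Synthetic herd simulator.

Generates the three data streams the fusion pipeline consumes — a
ground-truth visit schedule for one mechanical brush shared by a pen of
cows, the rotation-event log that brush produces, and noisy identity
detection streams emulating a camera (dense, low miss rate) and a
low-frequency RFID reader (sparse, high miss rate) mounted at the brush —
plus the exact ground truth needed to score every downstream stage.

The default configuration emulates a 24-cow pen observed for 3 days in
which individual daily brush use spans roughly one to twenty-seven minutes.
Visit and event micro-structure distributions (lognormal visit durations,
gamma event durations, exponential intra-visit gaps) are modelling
stand-ins: no public dataset describes these quantities, so the families
were chosen for their usual role as positive, right-skewed duration models
and their scales set so that simulated daily totals bracket the range
reported from direct observation of such pens (~59–1610 s per cow per day).

Structural guarantees the pipeline relies on:

* one brush → primary visits never overlap pen-wide;
* intra-visit gaps between rotation events are < 10 s, so a visit is never
  split by the inactivity rule;
* consecutive visits are separated either by a "quick succession" gap of
  < 10 s (always a different cow, creating user-change bout boundaries the
  rotation stream alone cannot resolve) or by a gap > 10 s (creating
  inactivity boundaries).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .records import SECONDS_PER_DAY

__all__ = [
    "SimConfig",
    "GroundTruth",
    "generate_schedule",
    "emit_rotation_events",
    "emit_detections",
    "derive_ground_truth",
    "simulate_all",
]

# sub-stream identifiers so each emitter is deterministic in (seed, stage)
_STREAM_SCHEDULE = 11
_STREAM_EVENTS = 23
_STREAM_DETECTIONS = {"vision": 37, "rfid": 41}

#: Shortest gap (s) separating visits that are *not* in quick succession;
#: keeps inactivity boundaries strictly above the 10 s rule.
_MIN_SLOW_GAP = 10.5

_QUICK_GAP_LO, _QUICK_GAP_HI = 0.5, 9.5


@dataclass
class SimConfig:
    """Parameters of the synthetic pen.

    Rates and probabilities are per the glossary in :mod:`brushfuse.simulate`;
    all times are seconds.  ``detection_period_s`` and ``miss_prob`` are
    per-source maps covering the vision (fiducial-marker camera) and RFID
    noise profiles.
    """

    n_cows: int = 24
    n_days: int = 3
    seed: int = 0
    visits_per_cow_day: float = 4.0
    visit_duration_median_s: float = 60.0
    visit_duration_sigma: float = 0.9
    visit_duration_bounds: tuple[float, float] = (10.0, 1800.0)
    event_duration_mean_s: float = 5.0
    event_duration_shape: float = 2.0
    intra_visit_gap_mean_s: float = 0.5
    direction_flip_prob: float = 0.8
    quick_succession_prob: float = 0.2
    detection_period_s: dict = field(
        default_factory=lambda: {"vision": 1.0, "rfid": 3.0}
    )
    miss_prob: dict = field(default_factory=lambda: {"vision": 0.1, "rfid": 0.5})
    jitter_sd_s: float = 0.3
    bystander_rate_per_hour: float = 6.0
    co_use_prob: float = 0.05

    def validate(self) -> None:
        if self.n_cows < 2:
            raise ValueError("n_cows must be >= 2")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        probs = [
            self.direction_flip_prob,
            self.quick_succession_prob,
            self.co_use_prob,
            *self.miss_prob.values(),
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        scales = [
            self.visit_duration_median_s,
            self.event_duration_mean_s,
            self.event_duration_shape,
            self.intra_visit_gap_mean_s,
            *self.detection_period_s.values(),
        ]
        if any(s <= 0 for s in scales):
            raise ValueError("scale parameters must be positive")
        if self.visits_per_cow_day < 0 or self.bystander_rate_per_hour < 0:
            raise ValueError("rates must be non-negative")
        if self.jitter_sd_s < 0:
            raise ValueError("jitter_sd_s must be non-negative")

    def replace(self, **kwargs) -> "SimConfig":
        d = asdict(self)
        d.update(kwargs)
        return SimConfig(**d)

    @classmethod
    def noiseless(cls, **kwargs) -> "SimConfig":
        """Profile with every stochastic confusion channel switched off.

        Detections are exhaustive and exactly periodic, there are no
        bystanders or shared visits, and no quick-succession visit pairs —
        the latter because a user change after a sub-10 s gap is undecidable
        from rotation data alone (the label depends on identity information
        the boundary classifier never sees), so it is a confusion channel,
        not an attribution noise level.
        """
        base = dict(
            miss_prob={"vision": 0.0, "rfid": 0.0},
            jitter_sd_s=0.0,
            bystander_rate_per_hour=0.0,
            co_use_prob=0.0,
            quick_succession_prob=0.0,
        )
        base.update(kwargs)
        return cls(**base)


@dataclass
class GroundTruth:
    """Exact per-event truth derived from a schedule + event stream.

    ``event_users`` holds one frozenset of animal ids per event (the primary
    visitor, plus the co-user when the event midpoint falls inside a shared
    stretch of the visit).  ``boundary`` marks bout starts: the first event,
    any change of user set, or any event after > 10 s of brush inactivity.
    ``bouts`` are ``(first_index, last_index_exclusive)`` runs.  ``daily_use``
    credits each animal with the full duration of every event it was using.
    """

    event_users: list
    boundary: np.ndarray
    bouts: list
    daily_use: pd.DataFrame


def _cow_ids(n_cows: int) -> list[str]:
    return [f"cow{idx:02d}" for idx in range(n_cows)]


def _truncated_lognormal(
    rng: np.random.Generator, median: float, sigma: float,
    bounds: tuple[float, float], size: int,
) -> np.ndarray:
    out = np.empty(size)
    lo, hi = bounds
    filled = 0
    while filled < size:
        draw = rng.lognormal(mean=np.log(median), sigma=sigma, size=size - filled)
        ok = draw[(draw >= lo) & (draw <= hi)]
        out[filled : filled + len(ok)] = ok
        filled += len(ok)
    return out


def generate_schedule(config: SimConfig) -> pd.DataFrame:
    """Draw the ground-truth visit schedule.

    Returns a frame with one row per visit: ``cow_id``, ``day``, ``start_s``,
    ``end_s`` (absolute seconds from simulation start), ``co_user`` (empty
    string or a second animal sharing part of the visit), ``co_start_s``,
    ``co_end_s``.  Visits are non-overlapping pen-wide; each day is packed
    independently by drawing per-cow visit counts (Poisson) and durations
    (truncated lognormal), shuffling the visit order, and spacing visits with
    either quick-succession gaps (< 10 s, different cow) or slow gaps whose
    lengths are an exponential-spacing partition of the remaining free time.
    """
    config.validate()
    rng = np.random.default_rng([_STREAM_SCHEDULE, config.seed])
    cows = _cow_ids(config.n_cows)
    rows = []
    for day in range(config.n_days):
        counts = rng.poisson(config.visits_per_cow_day, size=config.n_cows)
        visit_cows = np.repeat(np.arange(config.n_cows), counts)
        rng.shuffle(visit_cows)
        n_visits = len(visit_cows)
        if n_visits == 0:
            continue
        durations = _truncated_lognormal(
            rng,
            config.visit_duration_median_s,
            config.visit_duration_sigma,
            config.visit_duration_bounds,
            n_visits,
        )
        quick = rng.random(n_visits - 1) < config.quick_succession_prob
        # quick succession requires a user change
        if n_visits > 1:
            same = visit_cows[1:] == visit_cows[:-1]
            quick &= ~same
        quick_gaps = rng.uniform(_QUICK_GAP_LO, _QUICK_GAP_HI, size=n_visits - 1)
        n_slow = int(n_visits - 1 - quick.sum()) + 2  # + leading/trailing gap
        budget = (
            SECONDS_PER_DAY
            - durations.sum()
            - quick_gaps[quick].sum()
            - _MIN_SLOW_GAP * n_slow
        )
        if budget <= 0:
            raise ValueError(
                "infeasible packing: requested visit time exceeds the day; "
                "lower visits_per_cow_day or visit durations"
            )
        raw = rng.exponential(1.0, size=n_slow)
        slow_gaps = _MIN_SLOW_GAP + budget * raw / raw.sum()

        slow_iter = iter(slow_gaps)
        t = next(slow_iter)
        day0 = day * SECONDS_PER_DAY
        for i in range(n_visits):
            start = day0 + t
            end = start + durations[i]
            cow = cows[int(visit_cows[i])]
            co_user, co_start, co_end = "", np.nan, np.nan
            if rng.random() < config.co_use_prob:
                others = [c for c in cows if c != cow]
                co_user = others[int(rng.integers(len(others)))]
                span = durations[i]
                co_start = start + rng.uniform(0.0, 0.5) * span
                co_end = co_start + rng.uniform(0.25, 1.0) * (end - co_start)
            rows.append((cow, day, start, end, co_user, co_start, co_end))
            t += durations[i]
            if i < n_visits - 1:
                t += quick_gaps[i] if quick[i] else next(slow_iter)
    sched = pd.DataFrame(
        rows,
        columns=["cow_id", "day", "start_s", "end_s", "co_user", "co_start_s", "co_end_s"],
    )
    return sched


def _truncated_exponential(
    rng: np.random.Generator, mean: float, upper: float, size: int
) -> np.ndarray:
    # inverse-CDF sampling of Exp(mean) conditioned on < upper
    u = rng.random(size)
    return -mean * np.log1p(-u * (1.0 - np.exp(-upper / mean)))


def emit_rotation_events(schedule: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Tile each visit with rotation events.

    Event durations are gamma distributed, intra-visit gaps truncated
    exponential (< 10 s), and each event flips rotation direction relative
    to its predecessor with probability ``direction_flip_prob``.  The last
    event of a visit is clipped so events exactly cover ``[start_s, end_s]``.
    All times land on the millisecond grid so CSV round-trips are exact.
    """
    config.validate()
    rng = np.random.default_rng([_STREAM_EVENTS, config.seed])
    starts, durs, dirs = [], [], []
    scale = config.event_duration_mean_s / config.event_duration_shape
    for visit in schedule.itertuples():
        # quantize inward to the ms grid so events stay inside the visit
        t = np.ceil(visit.start_s * 1000.0) / 1000.0
        end = np.floor(visit.end_s * 1000.0) / 1000.0
        direction = int(rng.integers(2))
        while t < end - 1e-9:
            dur = rng.gamma(config.event_duration_shape, scale)
            dur = round(min(max(dur, 0.2), end - t), 3)
            if dur <= 0:
                break
            starts.append(t)
            durs.append(dur)
            dirs.append("cw" if direction else "ccw")
            gap = _truncated_exponential(
                rng, config.intra_visit_gap_mean_s, 10.0 - 0.1, 1
            )[0]
            t = round(t + dur + round(gap, 3), 3)
            if t >= end - 0.25:
                break
            if rng.random() < config.direction_flip_prob:
                direction = 1 - direction
    events = pd.DataFrame(
        {
            "event_id": np.arange(len(starts)),
            "start_s": np.asarray(starts, dtype=float),
            "duration_s": np.asarray(durs, dtype=float),
            "direction": dirs,
        }
    )
    return events


def emit_detections(
    schedule: pd.DataFrame, config: SimConfig, source: str
) -> pd.DataFrame:
    """Simulate one identity-detection stream (``vision`` or ``rfid``).

    During every visit the user (and any co-user, during the shared stretch)
    is read once per ``detection_period_s`` with independent miss probability
    ``miss_prob`` and Gaussian timing jitter.  Bystander reads — animals near
    the brush without using it — arrive as a homogeneous Poisson process over
    the whole simulation, each naming a uniformly random animal other than
    the cow(s) visiting at that instant.
    """
    config.validate()
    if source not in _STREAM_DETECTIONS:
        raise ValueError(f"unknown source {source!r}")
    rng = np.random.default_rng([_STREAM_DETECTIONS[source], config.seed])
    period = float(config.detection_period_s[source])
    miss = float(config.miss_prob[source])
    times, animals = [], []

    def _emit_track(t0: float, t1: float, animal: str) -> None:
        n = int(np.floor((t1 - t0) / period)) + 1
        base = t0 + period * np.arange(n)
        if config.jitter_sd_s > 0:
            base = base + rng.normal(0.0, config.jitter_sd_s, size=n)
        else:
            rng.normal(0.0, 1.0, size=n)  # keep stream alignment across configs
        kept = base[rng.random(n) >= miss]
        times.extend(np.round(kept, 3).tolist())
        animals.extend([animal] * len(kept))

    for visit in schedule.itertuples():
        _emit_track(visit.start_s, visit.end_s, visit.cow_id)
        if visit.co_user:
            _emit_track(visit.co_start_s, visit.co_end_s, visit.co_user)

    total_s = config.n_days * SECONDS_PER_DAY
    n_bystanders = rng.poisson(config.bystander_rate_per_hour / 3600.0 * total_s)
    if n_bystanders:
        cows = _cow_ids(config.n_cows)
        t_by = np.sort(rng.uniform(0.0, total_s, size=n_bystanders))
        vs = schedule["start_s"].to_numpy()
        ve = schedule["end_s"].to_numpy()
        vc = schedule["cow_id"].to_numpy()
        idx = np.searchsorted(vs, t_by, side="right") - 1
        for t, i in zip(t_by, idx):
            busy = set()
            if i >= 0 and t <= ve[i]:
                busy.add(vc[i])
            pool = [c for c in cows if c not in busy]
            times.append(round(float(t), 3))
            animals.append(pool[int(rng.integers(len(pool)))])

    det = pd.DataFrame(
        {"time_s": times, "animal_id": animals, "source": source}
    ).sort_values("time_s", kind="stable").reset_index(drop=True)
    return det


def derive_ground_truth(schedule: pd.DataFrame, events: pd.DataFrame) -> GroundTruth:
    """Attach exact truth to an event stream generated from ``schedule``.

    Each event is mapped to its visit by midpoint containment; its true user
    set is the visit's primary cow plus the co-user when the midpoint falls
    in the shared stretch.  Boundary flags follow the bout rule: first event,
    user-set change, or preceding brush inactivity > 10 s.
    """
    vs = schedule["start_s"].to_numpy()
    ve = schedule["end_s"].to_numpy()
    starts = events["start_s"].to_numpy()
    durs = events["duration_s"].to_numpy()
    mids = starts + durs / 2.0
    idx = np.searchsorted(vs, mids, side="right") - 1
    users: list[frozenset] = []
    for k, i in enumerate(idx):
        if i < 0 or mids[k] > ve[i] + 1e-6:
            raise ValueError(f"event {k} (midpoint {mids[k]:.3f}) lies outside every visit")
        row = schedule.iloc[i]
        u = {row["cow_id"]}
        if row["co_user"] and row["co_start_s"] <= mids[k] <= row["co_end_s"]:
            u.add(row["co_user"])
        users.append(frozenset(u))

    n = len(events)
    boundary = np.zeros(n, dtype=bool)
    if n:
        boundary[0] = True
        ends = starts + durs
        gaps = starts[1:] - ends[:-1]
        for k in range(1, n):
            boundary[k] = (users[k] != users[k - 1]) or (gaps[k - 1] > 10.0)

    bound_idx = np.flatnonzero(boundary)
    bouts = [
        (int(lo), int(hi))
        for lo, hi in zip(bound_idx, list(bound_idx[1:]) + [n])
    ]

    day = (starts // SECONDS_PER_DAY).astype(int) if n else np.array([], dtype=int)
    rows: dict[tuple[str, int], float] = {}
    for k in range(n):
        for cow in users[k]:
            key = (cow, int(day[k]))
            rows[key] = rows.get(key, 0.0) + durs[k]
    daily = pd.DataFrame(
        [(c, d, s) for (c, d), s in sorted(rows.items())],
        columns=["cow_id", "day", "seconds"],
    )
    return GroundTruth(event_users=users, boundary=boundary, bouts=bouts, daily_use=daily)


def simulate_all(config: SimConfig) -> dict:
    """Run the whole simulator; returns schedule, events, both detection
    streams and ground truth in one dict keyed by name."""
    schedule = generate_schedule(config)
    events = emit_rotation_events(schedule, config)
    truth = derive_ground_truth(schedule, events)
    return {
        "schedule": schedule,
        "events": events,
        "detections_vision": emit_detections(schedule, config, "vision"),
        "detections_rfid": emit_detections(schedule, config, "rfid"),
        "truth": truth,
    }
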