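"""Synthetic driving-session cohorts with drowsiness-dependent signal statistics.

The generator emulates a 9-driver simulator protocol: per driver one 1-h
session without sleep deprivation (NSD) and two 1-h sessions with sleep
deprivation (WSD), every session labeled every 300 s through the supervised-KSS
pipeline.  A latent per-interval drowsiness level in [0, 1] drives all four
channels:

* lateral position — mean-reverting (Ornstein–Uhlenbeck) noise around the lane
  center whose stationary deviation grows with drowsiness;
* steering angle — a smooth curvature-following component plus high-frequency
  micro-corrections that shrink with drowsiness and sporadic large corrective
  turns whose rate grows with it;
* heading error — a smoothed, scaled lateral-velocity proxy (clipped to the
  plausible −10°..6° range), correlated with the lateral channel;
* eye closure — a blink process (closures ≤ 0.4 s, excluded by PERCLOS) plus
  slow closure episodes budgeted so window PERCLOS stays within 0–0.11 when
  alert and roughly 0.05–0.50 when drowsy.

Drivers differ by a fixed susceptibility factor (a few drivers barely drowse,
one drowses heavily), and WSD drowsiness drifts upward with time on task; the
defaults put the cohort's drowsy-interval share near 0.29.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import lfilter

from .ground_truth import (
    ALERT,
    DISCARDED,
    DROWSY,
    KSSRecord,
    LabeledInterval,
    WindowDataset,
    build_window_dataset,
    label_interval,
)
from .signal_core import Condition, RoadGeometry, Session

__all__ = [
    "CohortConfig",
    "Cohort",
    "drowsiness_profile",
    "simulate_session",
    "generate_cohort",
    "generate_planted_lanex_dataset",
]

_GEOM = RoadGeometry()

#: fixed per-driver susceptibility to drowsiness under sleep deprivation;
#: two drivers are nearly immune, one is highly susceptible, mirroring the
#: spread seen across real cohorts
DEFAULT_SUSCEPTIBILITIES = (1.05, 0.95, 1.10, 0.15, 0.90, 0.25, 1.30, 0.85, 1.00)


@dataclass
class CohortConfig:
    """Cohort protocol and signal-statistics configuration.

    The defaults reproduce the study conditions: 9 drivers x (1 NSD + 2 WSD)
    1-h sessions at 30 Hz, labels every 300 s, ~3% interval dropout and a
    drowsy share near 0.291 of retained intervals.
    """

    n_drivers: int = 9
    nsd_sessions: int = 1
    wsd_sessions: int = 2
    session_s: float = 3600.0
    interval_s: float = 300.0
    sample_rate: float = 30.0
    drowsy_fraction: float = 0.291  # calibration target, not a dial
    dropout_rate: float = 0.03
    expert_error_prob: float = 0.05
    kss_noise: float = 0.7
    susceptibilities: Sequence[float] = DEFAULT_SUSCEPTIBILITIES
    # road curvature profile: two slow sinusoids (amplitude deg, period s)
    curvature_amplitudes: tuple[float, float] = (20.0, 10.0)
    curvature_periods: tuple[float, float] = (37.0, 89.0)
    nominal_speed_kmh: float = 90.0

    @property
    def intervals_per_session(self) -> int:
        return int(round(self.session_s / self.interval_s))


@dataclass
class Cohort:
    """A generated cohort: sessions, labels and the expanded data points."""

    sessions: dict[str, Session]
    intervals: list[LabeledInterval]
    kss_records: list[KSSRecord]
    dataset: WindowDataset
    config: CohortConfig
    seed: int

    @property
    def drowsy_fraction(self) -> float:
        kept = [iv for iv in self.intervals if iv.label != DISCARDED]
        return sum(iv.label == DROWSY for iv in kept) / len(kept)


def drowsiness_profile(
    condition: Condition | str,
    n_intervals: int,
    susceptibility: float,
    rng: np.random.Generator,
    wsd_hour_offset: float = 0.0,
) -> np.ndarray:
    """Latent per-interval drowsiness level in [0, 1].

    NSD sessions stay low; WSD sessions drift upward with time on task
    (``wsd_hour_offset`` hours already driven under deprivation), scaled by
    the driver's susceptibility.  Level > 0.5 is the drowsy ground truth.
    """
    condition = Condition(condition)
    if condition is Condition.NSD:
        base = susceptibility * 0.12 * np.ones(n_intervals)
        return np.clip(base + rng.normal(0.0, 0.05, n_intervals), 0.0, 0.45)
    t_h = wsd_hour_offset + (np.arange(n_intervals) + 0.5) * (300.0 / 3600.0)
    base = susceptibility * (0.24 + 0.30 * t_h)
    return np.clip(base + rng.normal(0.0, 0.06, n_intervals), 0.0, 1.0)


def _ou_process(
    rng: np.random.Generator,
    n: int,
    sd_per_sample: np.ndarray,
    theta: float,
    dt: float,
) -> np.ndarray:
    """Zero-mean OU path with per-sample target stationary deviation."""
    a = 1.0 - theta * dt
    sigma = sd_per_sample * np.sqrt(2.0 * theta * dt)
    u = sigma * rng.standard_normal(n)
    x0 = sd_per_sample[0] * rng.standard_normal()
    y, _ = lfilter([1.0], [1.0, -a], u, zi=np.array([a * x0]))
    return y


def _eye_closure_channel(
    rng: np.random.Generator,
    levels_per_block: np.ndarray,
    expression_per_block: np.ndarray,
    block_s: float,
    rate: float,
) -> np.ndarray:
    """Blink process plus budgeted slow-closure episodes, per 30-s block.

    ``expression_per_block`` scales how strongly a drowsy interval shows in
    the eyes: some drowsy drivers keep their eyes comparatively open, which
    puts part of the drowsy population inside the alert PERCLOS range.
    """
    block_n = int(round(block_s * rate))
    n = block_n * len(levels_per_block)
    eye = np.clip(np.abs(rng.normal(0.04, 0.025, n)), 0.0, 0.25)
    # blinks: short full closures, excluded by the PERCLOS blink rule
    n_blinks = rng.poisson(0.25 * n / rate)
    starts = rng.integers(0, n, size=n_blinks)
    durs = (rng.uniform(0.10, 0.35, size=n_blinks) * rate).astype(int)
    for s, d in zip(starts, durs):
        eye[s : s + max(d, 1)] = rng.uniform(0.85, 1.0)
    # slow closures: per-block closed-time budget driven by the latent level
    for b, (lvl, expr) in enumerate(zip(levels_per_block, expression_per_block)):
        if lvl <= 0.5:
            q = min((0.012 + 0.14 * lvl) * rng.uniform(0.6, 1.4), 0.095)
        else:
            q = float(np.clip((0.06 + 0.50 * (lvl - 0.5)) * expr * rng.uniform(0.8, 1.2),
                              0.055, 0.45))
        closed = q * block_s
        if closed <= 0.05:
            continue
        k = max(1, min(int(closed / 0.7), 6))
        durations = np.full(k, closed / k)
        slot = block_s / k
        base = b * block_n
        for e in range(k):
            dur_n = int(round(durations[e] * rate))
            if dur_n < 1:
                continue
            max_off = max(int(slot * rate) - dur_n, 0)
            off = int(rng.integers(0, max_off + 1))
            s = base + e * int(slot * rate) + off
            eye[s : s + dur_n] = np.clip(rng.normal(0.95, 0.03, dur_n), 0.85, 1.0)
    return np.clip(eye, 0.0, 1.0)


def simulate_session(
    subject_id: str,
    condition: Condition | str,
    profile: np.ndarray,
    seed: int | np.random.Generator,
    config: CohortConfig | None = None,
    session_id: str | None = None,
) -> tuple[Session, list[LabeledInterval], list[KSSRecord]]:
    """Generate one session whose per-interval statistics follow ``profile``.

    Returns the session, its supervised labels and the raw KSS records.
    Bit-identical under the same seed.
    """
    config = config or CohortConfig()
    condition = Condition(condition)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rate = config.sample_rate
    dt = 1.0 / rate
    n = int(round(config.session_s * rate))
    interval_n = int(round(config.interval_s * rate))
    n_intervals = config.intervals_per_session
    profile = np.asarray(profile, dtype=float)
    if len(profile) != n_intervals:
        raise ValueError(f"profile must have {n_intervals} interval levels")
    level = np.repeat(profile, interval_n)

    # lateral position: OU around the lane center, deviation grows with level;
    # a per-interval factor adds day-to-day variability so sibling windows of
    # one interval correlate
    lat_factor = np.repeat(rng.uniform(0.80, 1.30, n_intervals), interval_n)
    lat_sd = (0.17 + 0.17 * level) * lat_factor
    lateral = _GEOM.lane_center + _ou_process(rng, n, lat_sd, theta=0.3, dt=dt)
    lateral = np.clip(lateral, 0.05, _GEOM.lane_width - 0.05)

    # heading error: smoothed scaled lateral velocity, slight rightward bias
    lat_speed = np.empty(n)
    lat_speed[1:] = np.diff(lateral) * rate
    lat_speed[0] = lat_speed[1]
    smoothed = uniform_filter1d(lat_speed, size=int(rate), mode="nearest")
    heading = -1.0 + 6.0 * smoothed + rng.normal(0.0, 0.8, n)
    heading = np.clip(heading, -10.0, 6.0)

    # steering: curvature following + micro-corrections + sporadic large turns
    t = np.arange(n) * dt
    a1, a2 = config.curvature_amplitudes
    p1, p2 = config.curvature_periods
    ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
    curvature = a1 * np.sin(2 * np.pi * t / p1 + ph1) + a2 * np.sin(2 * np.pi * t / p2 + ph2) - 15.0
    micro_sd = 0.21 * (1.0 - 0.9 * level)
    rho = 0.8
    innov = micro_sd * np.sqrt(1 - rho**2) * rng.standard_normal(n)
    micro = lfilter([1.0], [1.0, -rho], innov)
    steering = curvature + micro
    # alert drivers also make occasional corrective turns; the rate rises
    # with drowsiness
    jerk_rate = 0.05 + 0.30 * np.maximum(level - 0.30, 0.0)  # events per second
    n_jerks = rng.poisson(jerk_rate.mean() * config.session_s)
    if n_jerks:
        # place jerks preferentially where the level is high
        w = jerk_rate + 1e-12
        starts = rng.choice(n, size=n_jerks, p=w / w.sum())
        for s in starts:
            dur = int(rng.uniform(0.3, 0.8) * rate)
            amp = rng.uniform(10.0, 30.0) * rng.choice([-1.0, 1.0])
            stop = min(s + dur, n)
            bump = amp * np.sin(np.pi * np.arange(stop - s) / dur)
            steering[s:stop] += bump
    steering = np.clip(steering, -120.0, 90.0)

    # eye-closure "expression": ~30% of drowsy intervals show only weakly
    expr = np.where(
        (profile > 0.5) & (rng.random(n_intervals) < 0.20),
        rng.uniform(0.30, 0.65, n_intervals),
        rng.uniform(0.80, 1.30, n_intervals),
    )
    blocks_per_interval = int(config.interval_s / 30.0)
    eye = _eye_closure_channel(
        rng,
        np.repeat(profile, blocks_per_interval),
        np.repeat(expr, blocks_per_interval),
        30.0,
        rate,
    )

    session = Session(
        subject_id=subject_id,
        condition=condition,
        sample_rate=rate,
        lateral_position=lateral,
        steering_angle=steering,
        heading_error=heading,
        eye_closure=eye[:n],
    )

    intervals: list[LabeledInterval] = []
    records: list[KSSRecord] = []
    for j, lvl in enumerate(profile):
        # KSS 7 is the ambiguous boundary rating, so it maps to level 0.5
        kss = int(np.clip(round(1.0 + 12.0 * lvl + rng.normal(0.0, config.kss_noise)), 1, 9))
        truth = DROWSY if lvl > 0.5 else ALERT
        other = ALERT if truth == DROWSY else DROWSY
        votes = tuple(
            other if rng.random() < config.expert_error_prob else truth for _ in range(3)
        )
        rec = KSSRecord(
            subject_id=subject_id,
            session_id=session_id,
            t=j * config.interval_s,
            kss=kss,
            expert_votes=votes,  # type: ignore[arg-type]
        )
        records.append(rec)
        intervals.append(label_interval(rec))
    return session, intervals, records


def generate_cohort(config: CohortConfig | None = None, seed: int = 0) -> Cohort:
    """Generate the full cohort and its expanded labeled data points.

    Default configuration: 9 drivers x 3 one-hour sessions (27 h, WSD:NSD
    hours 2:1), 12 label intervals per hour (324 before dropout), drowsy
    share of retained intervals near 0.291.
    """
    config = config or CohortConfig()
    master = np.random.default_rng(seed)
    sessions: dict[str, Session] = {}
    intervals: list[LabeledInterval] = []
    records: list[KSSRecord] = []
    for d in range(config.n_drivers):
        subject = f"U{d + 1}"
        susceptibility = config.susceptibilities[d % len(config.susceptibilities)]
        plan = [(Condition.NSD, 0.0)] * config.nsd_sessions + [
            (Condition.WSD, h * (config.session_s / 3600.0)) for h in range(config.wsd_sessions)
        ]
        for s_idx, (cond, offset) in enumerate(plan):
            session_id = f"{subject}_S{s_idx + 1}"
            rng = np.random.default_rng(master.integers(0, 2**31 - 1))
            profile = drowsiness_profile(
                cond, config.intervals_per_session, susceptibility, rng, wsd_hour_offset=offset
            )
            sess, ivs, recs = simulate_session(
                subject, cond, profile, rng, config, session_id=session_id
            )
            # simulator/vehicle data loss: a few intervals become discarded
            ivs = [
                LabeledInterval(iv.subject_id, iv.start, DISCARDED, iv.duration, iv.session_id)
                if master.random() < config.dropout_rate
                else iv
                for iv in ivs
            ]
            sessions[session_id] = sess
            intervals.extend(ivs)
            records.extend(recs)
    dataset = build_window_dataset(sessions, intervals)
    return Cohort(sessions, intervals, records, dataset, config, seed)


def generate_planted_lanex_dataset(
    x_L: float = 2.45,
    x_R: float = 1.30,
    n_drivers: int = 6,
    intervals_per_driver: int = 8,
    seed: int = 0,
    window_samples: int = 900,
    rate: float = 30.0,
) -> WindowDataset:
    """Windows whose lateral channel separates the classes exactly at a pair
    of planted virtual lines — a parameter-recovery benchmark for the GA.

    Alert windows never leave the band [x_R + 0.04, x_L − 0.04] (hard clip,
    so shifting a line into the band floods it with false positives); drowsy
    windows make brief excursions 0.02–0.08 m beyond one line, alternating
    sides window by window (so both lines must be recovered to detect every
    drowsy window).  The objective is maximal only when both searched lines
    sit within about ±0.1 m of the planted ones.
    """
    rng = np.random.default_rng(seed)
    center = (x_L + x_R) / 2.0
    rows, labels, subjects, session_ids, interval_ids, starts = [], [], [], [], [], []
    interval_id = 0
    for d in range(n_drivers):
        subject = f"P{d + 1}"
        for iv in range(intervals_per_driver):
            drowsy = iv % 2 == 1
            for w in range(10):
                base = center + _ou_process(
                    rng, window_samples, np.full(window_samples, 0.5), theta=0.5, dt=1.0 / rate
                )
                lat = np.clip(base, x_R + 0.04, x_L - 0.04)
                if drowsy:
                    left_side = w % 2 == 0
                    for _ in range(int(rng.integers(3, 6))):
                        dur = int(rng.uniform(0.4, 0.9) * rate)
                        s = int(rng.integers(0, window_samples - dur))
                        depth = rng.uniform(0.02, 0.08)
                        pos = (x_L + depth) if left_side else (x_R - depth)
                        lat[s : s + dur] = pos + rng.normal(0.0, 0.004, dur)
                rows.append(lat.astype(np.float32))
                labels.append(drowsy)
                subjects.append(subject)
                session_ids.append(f"{subject}_S1")
                interval_ids.append(interval_id)
                starts.append(iv * 300.0 + w * 30.0)
            interval_id += 1
    n = len(rows)
    lateral = np.array(rows, dtype=np.float32)
    channels = {
        "lateral_position": lateral,
        "steering_angle": rng.normal(0.0, 1.0, size=lateral.shape).astype(np.float32),
        "heading_error": np.clip(rng.normal(0.0, 1.0, size=lateral.shape), -10, 6).astype(np.float32),
        "eye_closure": np.clip(np.abs(rng.normal(0.05, 0.02, size=lateral.shape)), 0, 1).astype(np.float32),
    }
    return WindowDataset(
        subject_ids=np.array(subjects),
        session_ids=np.array(session_ids),
        interval_ids=np.array(interval_ids, dtype=int),
        start_s=np.array(starts),
        labels=np.array(labels),
        channels=channels,
        sample_rate=rate,
        window_s=window_samples / rate,
    )
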