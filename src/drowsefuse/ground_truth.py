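"""Supervised-KSS ground truth: label model and window-level expansion.

Drivers self-rate sleepiness on the 9-point Karolinska Sleepiness Scale (KSS)
every 5 minutes.  The rating is binarized (1–6 alert, 8–9 drowsy, 7
discarded) and then supervised by three trained experts whose majority vote
fixes the final label of the 300-s interval.  Each retained interval is
split into ten 30-s windows, every one carrying the interval label; those
(window, label) pairs are the data points all classifiers are trained and
scored on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .signal_core import CHANNEL_NAMES, Session, sliding_windows

__all__ = [
    "ALERT",
    "DROWSY",
    "DISCARDED",
    "KSSRecord",
    "LabeledInterval",
    "DataPoint",
    "WindowDataset",
    "binarize_kss",
    "supervise",
    "label_interval",
    "expand_to_datapoints",
    "build_window_dataset",
    "write_labels",
    "read_labels",
]

ALERT = "alert"
DROWSY = "drowsy"
DISCARDED = "discarded"

INTERVAL_S = 300.0


@dataclass(frozen=True)
class KSSRecord:
    """One KSS self-rating plus the three expert votes for a 300-s interval."""

    subject_id: str
    t: float  # interval start time within the session (s)
    kss: int
    expert_votes: tuple[str, str, str]
    session_id: str | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.kss <= 9:
            raise ValueError("kss must lie in [1, 9]")
        if len(self.expert_votes) != 3:
            raise ValueError("exactly 3 expert votes are required")
        if any(v not in (ALERT, DROWSY) for v in self.expert_votes):
            raise ValueError("expert votes must be 'alert' or 'drowsy'")


@dataclass(frozen=True)
class LabeledInterval:
    """A 300-s span of one session with one final binary (or discarded) label."""

    subject_id: str
    start: float  # s, within the session
    label: str
    duration: float = INTERVAL_S
    session_id: str | None = None

    def __post_init__(self) -> None:
        if self.label not in (ALERT, DROWSY, DISCARDED):
            raise ValueError(f"unknown label {self.label!r}")


@dataclass(frozen=True)
class DataPoint:
    """One labeled 30-s window (1/10 of a labeled interval)."""

    subject_id: str
    session_id: str | None
    interval_index: int
    start_s: float
    window_s: float
    label: str


def binarize_kss(kss: int) -> str:
    """Binarize a KSS rating: 1–6 alert, 8–9 drowsy, 7 discarded."""
    if not 1 <= int(kss) <= 9:
        raise ValueError(f"KSS rating must lie in [1, 9], got {kss}")
    kss = int(kss)
    if kss <= 6:
        return ALERT
    if kss == 7:
        return DISCARDED
    return DROWSY


def supervise(kss_binary: str, expert_votes: Sequence[str]) -> str:
    """Final supervised label: majority of the three expert votes.

    A discarded binarized KSS stays discarded regardless of the votes; the
    binarized rating itself is advisory input to the experts, whose majority
    is final.
    """
    if len(expert_votes) != 3:
        raise ValueError("exactly 3 expert votes are required")
    if kss_binary == DISCARDED:
        return DISCARDED
    n_drowsy = sum(1 for v in expert_votes if v == DROWSY)
    return DROWSY if n_drowsy >= 2 else ALERT


def label_interval(record: KSSRecord) -> LabeledInterval:
    """Apply binarization + expert vote to one KSS record."""
    return LabeledInterval(
        subject_id=record.subject_id,
        start=record.t,
        label=supervise(binarize_kss(record.kss), record.expert_votes),
        session_id=record.session_id,
    )


def expand_to_datapoints(
    intervals: Sequence[LabeledInterval],
    window_s: float = 30.0,
) -> list[DataPoint]:
    """Split each non-discarded interval into ``duration / window_s`` labeled windows."""
    points: list[DataPoint] = []
    for idx, iv in enumerate(intervals):
        if iv.label == DISCARDED:
            continue
        n = iv.duration / window_s
        n_int = int(round(n))
        if abs(n - n_int) > 1e-9 or n_int < 1:
            raise ValueError("interval duration must be an integer multiple of window_s")
        for j in range(n_int):
            points.append(
                DataPoint(
                    subject_id=iv.subject_id,
                    session_id=iv.session_id,
                    interval_index=idx,
                    start_s=iv.start + j * window_s,
                    window_s=window_s,
                    label=iv.label,
                )
            )
    return points


@dataclass
class WindowDataset:
    """Labeled 30-s windows with their raw channel samples, in matrix form.

    ``channels[name]`` is an ``(n_points, window_samples)`` float32 matrix;
    ``labels`` is boolean with drowsy = True.  This is the container the
    threshold classifiers and the GA operate on.
    """

    subject_ids: np.ndarray  # (n,) str
    session_ids: np.ndarray  # (n,) str
    interval_ids: np.ndarray  # (n,) int — index into the source interval list
    start_s: np.ndarray  # (n,) float
    labels: np.ndarray  # (n,) bool, drowsy = True
    channels: dict[str, np.ndarray]
    sample_rate: float = 30.0
    window_s: float = 30.0

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def subjects(self) -> np.ndarray:
        return np.unique(self.subject_ids)

    def subset(self, index: np.ndarray) -> "WindowDataset":
        return WindowDataset(
            subject_ids=self.subject_ids[index],
            session_ids=self.session_ids[index],
            interval_ids=self.interval_ids[index],
            start_s=self.start_s[index],
            labels=self.labels[index],
            channels={k: v[index] for k, v in self.channels.items()},
            sample_rate=self.sample_rate,
            window_s=self.window_s,
        )


def build_window_dataset(
    sessions: Mapping[str, Session],
    intervals: Sequence[LabeledInterval],
    window_s: float = 30.0,
) -> WindowDataset:
    """Expand intervals to data points and slice the channel windows out of
    their sessions."""
    points = expand_to_datapoints(intervals, window_s)
    if not points:
        raise ValueError("no non-discarded intervals to expand")
    rate = next(iter(sessions.values())).sample_rate
    win = int(round(window_s * rate))
    n = len(points)
    channels = {name: np.empty((n, win), dtype=np.float32) for name in CHANNEL_NAMES}
    for i, p in enumerate(points):
        sess = sessions[p.session_id]
        start = int(round(p.start_s * sess.sample_rate))
        if start + win > sess.n_samples:
            raise ValueError(f"data point at {p.start_s} s extends past session {p.session_id}")
        for name in CHANNEL_NAMES:
            channels[name][i] = sess.channel(name)[start : start + win]
    return WindowDataset(
        subject_ids=np.array([p.subject_id for p in points]),
        session_ids=np.array([p.session_id for p in points]),
        interval_ids=np.array([p.interval_index for p in points], dtype=int),
        start_s=np.array([p.start_s for p in points]),
        labels=np.array([p.label == DROWSY for p in points]),
        channels=channels,
        sample_rate=rate,
        window_s=window_s,
    )


def write_labels(records: Sequence[KSSRecord], path: str | Path) -> None:
    """Write KSS records and their final labels as CSV."""
    rows = []
    for r in records:
        rows.append(
            {
                "subject_id": r.subject_id,
                "session_id": r.session_id or "",
                "start_s": r.t,
                "kss": r.kss,
                "vote1": r.expert_votes[0],
                "vote2": r.expert_votes[1],
                "vote3": r.expert_votes[2],
                "label": label_interval(r).label,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_labels(path: str | Path) -> tuple[list[KSSRecord], list[LabeledInterval]]:
    df = pd.read_csv(path, keep_default_na=False)
    records, intervals = [], []
    for _, row in df.iterrows():
        rec = KSSRecord(
            subject_id=str(row["subject_id"]),
            session_id=str(row["session_id"]) or None,
            t=float(row["start_s"]),
            kss=int(row["kss"]),
            expert_votes=(str(row["vote1"]), str(row["vote2"]), str(row["vote3"])),
        )
        records.append(rec)
        intervals.append(label_interval(rec))
    return records, intervals
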