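"""Driving-session data model, windowing, derivatives and session file I/O.

A :class:`Session` holds the four synchronized 30-Hz channels recorded for one
driver-hour in a driving simulator: vehicle-lane lateral position (m, measured
from the right lane boundary to the vehicle center, increasing leftward),
steering-wheel angle (deg, positive anticlockwise), heading error (deg,
positive when approaching the left lane boundary) and eye-closure fraction
(dimensionless, in [0, 1]).

All drowsiness indicators operate on fixed-length windows cut from these
channels; :func:`sliding_windows` and :func:`derivative` are the two shared
numerical primitives.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "Condition",
    "Session",
    "Window",
    "RoadGeometry",
    "CHANNEL_NAMES",
    "sliding_windows",
    "derivative",
    "read_session",
    "write_session",
]

CHANNEL_NAMES = ("lateral_position", "steering_angle", "heading_error", "eye_closure")

DEFAULT_SAMPLE_RATE = 30.0


class Condition(str, enum.Enum):
    """Sleep-deprivation condition of a driving session."""

    NSD = "NSD"  # without sleep deprivation
    WSD = "WSD"  # with sleep deprivation


@dataclass
class Session:
    """One driver-hour of synchronized 30-Hz simulator channels.

    Parameters
    ----------
    subject_id
        Driver identifier (e.g. ``"U7"``).
    condition
        Sleep-deprivation condition under which the session was driven.
    sample_rate
        Channel sampling rate in Hz.
    lateral_position
        Distance (m) from the right lane boundary to the vehicle center;
        non-negative, increasing leftward.
    steering_angle
        Steering-wheel angle (deg); 0 = centered, positive anticlockwise.
    heading_error
        Angle (deg) between vehicle heading and the lane tangent; positive
        means the vehicle is approaching the left lane boundary.
    eye_closure
        Eye-closure fraction per sample, in [0, 1] (1 = fully closed).
    """

    subject_id: str
    condition: Condition
    lateral_position: np.ndarray
    steering_angle: np.ndarray
    heading_error: np.ndarray
    eye_closure: np.ndarray
    sample_rate: float = DEFAULT_SAMPLE_RATE

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        self.condition = Condition(self.condition)
        for name in CHANNEL_NAMES:
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.ndim != 1:
                raise ValueError(f"channel {name!r} must be one-dimensional")
        lengths = {len(getattr(self, name)) for name in CHANNEL_NAMES}
        if len(lengths) != 1:
            raise ValueError(f"all channels must have identical length, got {lengths}")
        if np.any(self.eye_closure < 0) or np.any(self.eye_closure > 1):
            raise ValueError("eye_closure values must lie in [0, 1]")
        if np.any(self.lateral_position < 0):
            raise ValueError("lateral_position must be non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.lateral_position)

    @property
    def duration(self) -> float:
        """Session duration in seconds."""
        return self.n_samples / self.sample_rate

    def channel(self, name: str) -> np.ndarray:
        if name not in CHANNEL_NAMES:
            raise KeyError(f"unknown channel {name!r}; expected one of {CHANNEL_NAMES}")
        return getattr(self, name)


@dataclass(frozen=True)
class Window:
    """A contiguous span of samples inside one session channel."""

    start_index: int
    length: int
    source_channel: str = "lateral_position"

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("window length must be >= 1 sample")
        if self.start_index < 0:
            raise ValueError("window start_index must be >= 0")

    @property
    def stop_index(self) -> int:
        return self.start_index + self.length

    def slice(self, series: np.ndarray) -> np.ndarray:
        if self.stop_index > len(series):
            raise ValueError("window extends past the end of the series")
        return series[self.start_index : self.stop_index]


@dataclass(frozen=True)
class RoadGeometry:
    """Lane and vehicle geometry defining the physical lane-exit lines.

    With a ``lane_width`` lane and a ``vehicle_width`` vehicle, the left
    wheels touch the left lane line when the vehicle center sits at
    ``lane_width - vehicle_width / 2`` and the right wheels touch the right
    line at ``vehicle_width / 2``; those two positions are the physical
    left/right boundaries used by the lane-exit indicators.
    """

    lane_width: float = 3.75
    vehicle_width: float = 2.25

    @property
    def lane_center(self) -> float:
        return self.lane_width / 2.0

    @property
    def left_boundary(self) -> float:
        return self.lane_width - self.vehicle_width / 2.0

    @property
    def right_boundary(self) -> float:
        return self.vehicle_width / 2.0


def _samples(seconds: float, rate: float, what: str) -> int:
    n = seconds * rate
    n_int = int(round(n))
    if abs(n - n_int) > 1e-9 or n_int < 1:
        raise ValueError(f"{what} ({seconds} s at {rate} Hz) must be a whole number of samples >= 1")
    return n_int


def sliding_windows(
    series: np.ndarray | int,
    window_s: float,
    step_s: float,
    rate: float = DEFAULT_SAMPLE_RATE,
    source_channel: str = "lateral_position",
) -> list[Window]:
    """Enumerate fully contained windows of ``window_s`` seconds every ``step_s``.

    ``series`` may be the sample array itself or just its length.  Returns the
    maximal ordered list of windows fully inside the series; a series shorter
    than one window yields an empty list (not an error).
    """
    n = series if isinstance(series, (int, np.integer)) else len(series)
    win = _samples(window_s, rate, "window length")
    step = _samples(step_s, rate, "window step")
    starts = range(0, n - win + 1, step)
    return [Window(s, win, source_channel) for s in starts]


def derivative(series: np.ndarray, rate: float = DEFAULT_SAMPLE_RATE) -> np.ndarray:
    """First-order backward-difference derivative, in input units per second.

    Output has the same length as the input; element ``i >= 1`` equals
    ``(x[i] - x[i-1]) * rate`` and element 0 duplicates element 1 so that the
    causal estimate is defined everywhere.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("derivative requires a 1-D series of length >= 2")
    out = np.empty_like(x)
    out[1:] = np.diff(x) * rate
    out[0] = out[1]
    return out


# ---------------------------------------------------------------------------
# Session file I/O
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ("t",) + CHANNEL_NAMES


class SessionFormatError(ValueError):
    """Raised when a session file does not match the expected layout."""


def write_session(session: Session, path: str | Path, format: str | None = None) -> None:
    """Write a session to CSV (header ``t,<channels>``) or HDF5 (``/channels/<name>``)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        t = np.arange(session.n_samples) / session.sample_rate
        df = pd.DataFrame({"t": t})
        for name in CHANNEL_NAMES:
            df[name] = session.channel(name)
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write(f"# subject_id={session.subject_id} condition={session.condition.value} "
                     f"sample_rate={session.sample_rate}\n")
            df.to_csv(fh, index=False, float_format="%.10g")
    elif fmt == "hdf5":
        with h5py.File(path, "w") as f:
            grp = f.create_group("channels")
            for name in CHANNEL_NAMES:
                grp.create_dataset(name, data=session.channel(name))
            f.attrs["subject_id"] = session.subject_id
            f.attrs["condition"] = session.condition.value
            f.attrs["sample_rate"] = session.sample_rate
    else:  # pragma: no cover - _infer_format already validates
        raise SessionFormatError(f"unknown session format {fmt!r}")


def read_session(path: str | Path, format: str | None = None) -> Session:
    """Read a session written by :func:`write_session`."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        meta = {"subject_id": "unknown", "condition": "NSD", "sample_rate": DEFAULT_SAMPLE_RATE}
        with open(path, encoding="utf-8") as fh:
            first = fh.readline()
            if first.startswith("#"):
                for tok in first[1:].split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        if k in meta:
                            meta[k] = v
                df = pd.read_csv(fh)
            else:
                fh.seek(0)
                df = pd.read_csv(fh)
        missing = [c for c in _CSV_COLUMNS if c not in df.columns]
        if missing:
            raise SessionFormatError(f"session CSV {path} is missing column(s): {', '.join(missing)}")
        return Session(
            subject_id=str(meta["subject_id"]),
            condition=Condition(meta["condition"]),
            sample_rate=float(meta["sample_rate"]),
            **{name: df[name].to_numpy(dtype=float) for name in CHANNEL_NAMES},
        )
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            if "channels" not in f:
                raise SessionFormatError(f"HDF5 session {path} has no /channels group")
            grp = f["channels"]
            missing = [name for name in CHANNEL_NAMES if name not in grp]
            if missing:
                raise SessionFormatError(f"HDF5 session {path} is missing channel(s): {', '.join(missing)}")
            channels = {name: grp[name][...] for name in CHANNEL_NAMES}
            return Session(
                subject_id=str(f.attrs.get("subject_id", "unknown")),
                condition=Condition(str(f.attrs.get("condition", "NSD"))),
                sample_rate=float(f.attrs.get("sample_rate", DEFAULT_SAMPLE_RATE)),
                **channels,
            )
    raise SessionFormatError(f"unknown session format {fmt!r}")


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        fmt = format.lower()
        if fmt in ("h5", "hdf"):
            fmt = "hdf5"
        if fmt not in ("csv", "hdf5"):
            raise SessionFormatError(f"unknown session format {format!r}; expected 'csv' or 'hdf5'")
        return fmt
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return "csv"
    if suffix in (".h5", ".hdf5", ".hdf"):
        return "hdf5"
    raise SessionFormatError(f"cannot infer format from suffix {suffix!r}; pass format='csv' or 'hdf5'")
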