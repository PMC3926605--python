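"""Windowed drowsiness indicators.

Each indicator maps a 30-s window of one simulator channel onto a scalar:

* ``STD_lp`` / ``STD_sw`` / ``STD_he`` — sample standard deviation of lateral
  position, steering-wheel angle and heading error (SDLP is the classic
  driving-impairment marker).
* ``MSE_lp`` / ``MSE_he`` — root-mean-square deviation from a reference value
  ``p`` instead of the window mean (lane center 1.875 m; zero heading error).
* ``Lanex`` — fraction of samples outside a (possibly virtual) lane defined by
  the line positions ``x_L`` and ``x_R``.
* ``TLC_5s`` / ``TLC_avg`` — statistics of the per-sample time-to-line-crossing
  signal estimated from lateral position and lateral speed.
* ``RSWM`` — rapid steering-wheel movement: fraction of steering-speed samples
  exceeding a threshold ``d``.
* ``PERCLOS`` — fraction of a window during which the eye is more than 80%
  closed, excluding blinks.

Higher values indicate a drowsier driver for every indicator (the TLC average
is negated for that reason).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .signal_core import RoadGeometry, Session, Window, derivative, sliding_windows

__all__ = [
    "INDICATOR_NAMES",
    "INDICATOR_CHANNEL",
    "OPTIMIZABLE",
    "IndicatorParams",
    "IndicatorSeries",
    "std_indicator",
    "mse_indicator",
    "lanex",
    "tlc_series",
    "tlc_5s",
    "tlc_avg",
    "rswm",
    "perclos",
    "compute_window_value",
    "compute_indicator_series",
    "load_params_preset",
]

INDICATOR_NAMES = (
    "STD_lp", "STD_sw", "STD_he",
    "MSE_lp", "MSE_he",
    "Lanex", "TLC_5s", "TLC_avg",
    "RSWM", "PERCLOS",
)

#: which session channel each indicator consumes
INDICATOR_CHANNEL: Mapping[str, str] = {
    "STD_lp": "lateral_position",
    "MSE_lp": "lateral_position",
    "Lanex": "lateral_position",
    "TLC_5s": "lateral_position",
    "TLC_avg": "lateral_position",
    "STD_sw": "steering_angle",
    "RSWM": "steering_angle",
    "STD_he": "heading_error",
    "MSE_he": "heading_error",
    "PERCLOS": "eye_closure",
}

#: free parameters searched by the GA, per indicator (the decision threshold T
#: is always optimized jointly and is not listed here)
OPTIMIZABLE: Mapping[str, tuple[str, ...]] = {
    "MSE_lp": ("p",),
    "MSE_he": ("p",),
    "Lanex": ("x_L", "x_R"),
    "TLC_5s": ("a",),
    "RSWM": ("d",),
}

_GEOM = RoadGeometry()

_DEFAULT_BOUNDS: Mapping[str, tuple[float, float]] = {
    "p_MSE_lp": (1.0, 2.75),
    "p_MSE_he": (-5.0, 5.0),
    "x_L": (_GEOM.lane_center + 0.05, _GEOM.left_boundary),
    "x_R": (_GEOM.right_boundary, _GEOM.lane_center - 0.05),
    "a": (0.5, 15.0),
    "d": (1.0, 200.0),
}


@dataclass
class IndicatorParams:
    """Tunable constants of one indicator.

    Only the fields relevant to ``name`` are used.  ``p`` is the reference
    value of the root-mean-square indicators (m for lateral position, deg for
    heading error); ``x_L``/``x_R`` the virtual left/right line positions (m);
    ``a`` the TLC alarm threshold (s); ``d`` the steering-speed threshold
    (deg/s); ``tlc_max`` the TLC saturation value (s); ``closure_threshold``
    the eye-closure fraction above which the eye counts as closed; and
    ``blink_max`` the longest episode duration (s) still treated as a blink.
    ``threshold`` is the scalar decision threshold T applied to the indicator
    value for single-indicator classification (set by optimization).
    """

    name: str
    p: float = 0.0
    x_L: float = _GEOM.left_boundary
    x_R: float = _GEOM.right_boundary
    a: float = 5.0
    d: float = 125.0
    tlc_max: float = 30.0
    closure_threshold: float = 0.8
    blink_max: float = 0.5
    threshold: float | None = None
    bounds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in INDICATOR_NAMES:
            raise ValueError(f"unknown indicator {self.name!r}; expected one of {INDICATOR_NAMES}")
        if self.x_L <= self.x_R:
            raise ValueError("x_L must exceed x_R")
        if self.a <= 0 or self.d <= 0:
            raise ValueError("thresholds a and d must be positive")
        if self.tlc_max <= self.a:
            raise ValueError("tlc_max must exceed a")
        if not 0.0 < self.closure_threshold < 1.0:
            raise ValueError("closure_threshold must lie in (0, 1)")

    @classmethod
    def defaults(cls, name: str, **overrides) -> "IndicatorParams":
        """Literature defaults: p = lane center (MSE_lp) or 0 deg (MSE_he),
        physical lane lines, a = 5 s, d = 125 deg/s."""
        params = {"name": name}
        if name == "MSE_lp":
            params["p"] = _GEOM.lane_center
        elif name == "MSE_he":
            params["p"] = 0.0
        params.update(overrides)
        obj = cls(**params)
        obj.bounds = dict(obj.bounds) or obj.default_bounds()
        return obj

    @classmethod
    def table2_optimized(cls, name: str, **overrides) -> "IndicatorParams":
        """The optimized parameter preset reported for the original 9-driver
        simulator study: p = 1.865 m (MSE_lp) / −1.2 deg (MSE_he),
        virtual lines x_L = 2.27 m / x_R = 1.42 m, a = 6.4 s, d = 13 deg/s."""
        preset = {
            "MSE_lp": {"p": 1.865},
            "MSE_he": {"p": -1.2},
            "Lanex": {"x_L": 2.27, "x_R": 1.42},
            "TLC_5s": {"a": 6.4, "x_L": 2.27, "x_R": 1.42},
            "TLC_avg": {"x_L": 2.27, "x_R": 1.42},
            "RSWM": {"d": 13.0},
        }
        params = dict(preset.get(name, {}))
        params.update(overrides)
        return cls.defaults(name, **params)

    def default_bounds(self) -> dict[str, tuple[float, float]]:
        out: dict[str, tuple[float, float]] = {}
        for pname in OPTIMIZABLE.get(self.name, ()):
            key = f"{pname}_{self.name}" if f"{pname}_{self.name}" in _DEFAULT_BOUNDS else pname
            out[pname] = _DEFAULT_BOUNDS[key]
        return out

    def replace(self, **changes) -> "IndicatorParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bounds"] = {k: list(v) for k, v in self.bounds.items()}
        return d


@dataclass
class IndicatorSeries:
    """One scalar indicator value per window, stamped at the window end time."""

    name: str
    t_end: np.ndarray  # seconds
    values: np.ndarray
    params: IndicatorParams

    def __len__(self) -> int:
        return len(self.values)

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        arr = np.column_stack([self.t_end, self.values])
        header = "t_end_s,value"
        np.savetxt(path, arr, delimiter=",", header=header, comments="", fmt="%.10g")
        sidecar = path.with_suffix(path.suffix + ".params.json")
        sidecar.write_text(json.dumps(self.params.to_dict(), indent=1))


# ---------------------------------------------------------------------------
# scalar indicator kernels
# ---------------------------------------------------------------------------


def _check_window(values: np.ndarray, min_n: int = 2) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < min_n:
        raise ValueError(f"indicator window must be 1-D with at least {min_n} samples")
    return x


def std_indicator(values: np.ndarray) -> float:
    """Sample standard deviation with the n−1 denominator."""
    x = _check_window(values)
    return float(np.sqrt(np.sum((x - x.mean()) ** 2) / (len(x) - 1)))


def mse_indicator(values: np.ndarray, p: float) -> float:
    """Root-mean-square deviation from the reference ``p`` (n−1 denominator).

    Reduces to :func:`std_indicator` when ``p`` equals the window mean.
    """
    x = _check_window(values)
    return float(np.sqrt(np.sum((x - p) ** 2) / (len(x) - 1)))


def lanex(values: np.ndarray, x_L: float, x_R: float) -> float:
    """Fraction of samples strictly outside the (virtual) lane [x_R, x_L]."""
    if x_L <= x_R:
        raise ValueError("x_L must exceed x_R")
    x = _check_window(values, min_n=1)
    return float(np.mean((x > x_L) | (x < x_R)))


def tlc_series(
    lateral: np.ndarray,
    lateral_speed: np.ndarray,
    x_L: float = _GEOM.left_boundary,
    x_R: float = _GEOM.right_boundary,
    tlc_max: float = 30.0,
) -> np.ndarray:
    """Per-sample time to line crossing (s), saturated at ``tlc_max``.

    The distance to the right line d_R = x_R − x (negative inside the lane)
    is divided by the lateral speed when moving rightward (speed < 0), the
    distance to the left line d_L = x_L − x when moving leftward (speed > 0).
    Zero lateral speed yields ``tlc_max``; a vehicle already outside the
    virtual lane (d_L < 0 or d_R > 0) yields 0.
    """
    x = np.asarray(lateral, dtype=float)
    v = np.asarray(lateral_speed, dtype=float)
    if x.shape != v.shape:
        raise ValueError("lateral and lateral_speed windows must be aligned and equal length")
    d_R = x_R - x
    d_L = x_L - x
    with np.errstate(divide="ignore", invalid="ignore"):
        tlc = np.where(v < 0, d_R / v, np.where(v > 0, d_L / v, tlc_max))
    tlc = np.minimum(tlc, tlc_max)
    tlc[(d_L < 0) | (d_R > 0)] = 0.0
    return tlc


def tlc_5s(tlc: np.ndarray, a: float = 5.0) -> int:
    """Number of the first n−1 TLC samples falling below the alarm level ``a``."""
    t = _check_window(tlc)
    return int(np.sum(t[:-1] < a))


def tlc_avg(tlc: np.ndarray) -> float:
    """Negated mean of the TLC series (so that larger means drowsier)."""
    t = _check_window(tlc, min_n=1)
    return float(-np.mean(t))


def rswm(steering_speed: np.ndarray, d: float = 125.0) -> float:
    """Fraction of steering-speed samples 2..n whose magnitude exceeds ``d`` deg/s."""
    if d <= 0:
        raise ValueError("steering-speed threshold d must be positive")
    s = _check_window(steering_speed)
    return float(np.mean(np.abs(s[1:]) > d))


def perclos(
    eye_closure: np.ndarray,
    closure_threshold: float = 0.8,
    blink_max: float = 0.5,
    rate: float = 30.0,
) -> float:
    """Fraction of the window with the eye closed beyond ``closure_threshold``,
    excluding blink episodes no longer than ``blink_max`` seconds.

    Consecutive above-threshold samples form an episode; episodes whose
    duration (within the window, so edge-truncated episodes count their
    visible part) is at most ``blink_max`` are treated as blinks and removed.
    """
    x = _check_window(eye_closure, min_n=1)
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("eye-closure values must lie in [0, 1]")
    closed = x > closure_threshold
    if not closed.any():
        return 0.0
    # run-length encode the closed mask
    edges = np.diff(closed.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if closed[0]:
        starts = np.concatenate([[0], starts])
    if closed[-1]:
        ends = np.concatenate([ends, [len(x)]])
    lengths = ends - starts
    max_blink_samples = blink_max * rate
    retained = int(lengths[lengths > max_blink_samples].sum())
    return retained / len(x)


# ---------------------------------------------------------------------------
# session-level dispatch
# ---------------------------------------------------------------------------


def compute_window_value(
    name: str,
    window_values: np.ndarray,
    params: IndicatorParams,
    rate: float = 30.0,
    speed_window: np.ndarray | None = None,
) -> float:
    """Evaluate one indicator on one window of its source channel.

    ``speed_window`` (the channel derivative over the same window) is required
    by the TLC and RSWM indicators; when omitted it is computed from the
    window itself with edge padding.
    """
    if name in ("STD_lp", "STD_sw", "STD_he"):
        return std_indicator(window_values)
    if name in ("MSE_lp", "MSE_he"):
        return mse_indicator(window_values, params.p)
    if name == "Lanex":
        return lanex(window_values, params.x_L, params.x_R)
    if name in ("TLC_5s", "TLC_avg"):
        speed = speed_window if speed_window is not None else derivative(window_values, rate)
        tlc = tlc_series(window_values, speed, params.x_L, params.x_R, params.tlc_max)
        return float(tlc_5s(tlc, params.a)) if name == "TLC_5s" else tlc_avg(tlc)
    if name == "RSWM":
        speed = speed_window if speed_window is not None else derivative(window_values, rate)
        return rswm(speed, params.d)
    if name == "PERCLOS":
        return perclos(window_values, params.closure_threshold, params.blink_max, rate)
    raise ValueError(f"unknown indicator {name!r}")


def compute_indicator_series(
    session: Session,
    params: IndicatorParams,
    window_s: float = 30.0,
    step_s: float = 30.0,
) -> IndicatorSeries:
    """Slide a ``window_s`` window along the session's matching channel.

    Timestamps are window end times in seconds.  The channel derivative
    (needed by TLC and RSWM) is computed once over the whole session so that
    interior windows see the true backward difference at their first sample.
    """
    channel = session.channel(INDICATOR_CHANNEL[params.name])
    rate = session.sample_rate
    windows = sliding_windows(channel, window_s, step_s, rate)
    needs_speed = params.name in ("TLC_5s", "TLC_avg", "RSWM")
    speed = derivative(channel, rate) if needs_speed else None
    values = np.empty(len(windows))
    t_end = np.empty(len(windows))
    for i, w in enumerate(windows):
        sw = w.slice(speed) if needs_speed else None
        values[i] = compute_window_value(params.name, w.slice(channel), params, rate, sw)
        t_end[i] = w.stop_index / rate
    return IndicatorSeries(params.name, t_end, values, params)


def load_params_preset(preset: str | Path) -> dict[str, IndicatorParams]:
    """Load a per-indicator parameter preset.

    ``preset`` may be ``"defaults"``, ``"table2_optimized"`` or a path to a
    YAML file mapping indicator names to parameter overrides.
    """
    if preset == "defaults":
        return {name: IndicatorParams.defaults(name) for name in INDICATOR_NAMES}
    if preset in ("table2_optimized", "optimized"):
        return {name: IndicatorParams.table2_optimized(name) for name in INDICATOR_NAMES}
    path = Path(preset)
    raw = yaml.safe_load(path.read_text())
    out = {}
    for name, overrides in raw.items():
        out[name] = IndicatorParams.defaults(name, **(overrides or {}))
    return out
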