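"""Turn-maneuver detection and driving-performance signatures.

Turns are detected as significant peaks of the z-axis angular velocity.  The
series is lightly smoothed, peaks of the absolute value above a threshold
and separated by a minimum interval are located, and a fixed window of
samples on either side of each peak is analyzed: angular acceleration is the
centered finite difference of the smoothed angular velocity, and the turn
angle is the trapezoidal integral of the raw angular velocity between the
zero crossings bracketing the peak.  Events integrate to ~90 degrees or
~180 degrees; anything below the minor-angle cutoff, or falling inside a
detected U-turn's extent, is labeled minor and excluded from aggregates.

Speed at each peak comes from linear interpolation of the 1 Hz GPS speed at
the 10 Hz peak time.  Session-level signatures are per-kind means of the
per-event metrics; combined left+right values average the two side means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Iterable

import numpy as np
from scipy.signal import find_peaks

from .traces import GpsTrack, SensorTrace

__all__ = [
    "TurnConfig",
    "TurnEvent",
    "SignatureSet",
    "detect_turns",
    "speed_at_peaks",
    "uturn_period",
    "aggregate_signatures",
]


@dataclass
class TurnConfig:
    """Detector tuning.  Defaults give exactly 8 non-minor events per
    noiseless lap of the standardized circuit; all are adjustable."""

    peak_threshold: float = 0.15  # rad/s on the smoothed |angular velocity|
    min_separation_s: float = 3.0
    window_half_width: int = 15  # samples either side of the peak (1.5 s at 10 Hz)
    smooth_window: int = 5  # moving-average samples
    minor_angle_cutoff: float = 0.6 * math.pi / 2  # below this the event is minor
    uturn_angle_cutoff: float = 3.0 * math.pi / 4  # >= 135 degrees is a U-turn
    period_fraction: float = 0.1  # crossing level for the U-turn period
    left_positive: bool = True  # positive gyro z = left turn (ENU)
    resample: bool = False  # resample non-uniform traces to nominal_rate


@dataclass
class TurnEvent:
    """One detected maneuver and its kinematic metrics.

    ``peak_angular_velocity`` is signed (positive = left under the default
    convention).  Acceleration extremes are reported in the turn's own
    handedness frame (the signal multiplied by the sign of the peak), so
    left and right turns are directly comparable.
    """

    peak_time: float
    kind: str  # 'left90' | 'right90' | 'uturn180' | 'minor'
    peak_angular_velocity: float
    max_angular_acceleration: float
    min_angular_acceleration: float
    integrated_angle: float
    speed_at_peak: float = float("nan")
    speed_valid: bool = False
    period: float = float("nan")  # defined for uturn180
    window: tuple[float, float] = (float("nan"), float("nan"))
    extent: tuple[float, float] = (float("nan"), float("nan"))  # zero-crossing span


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.astype(float)
    pad = window // 2
    xp = np.pad(x.astype(float), pad, mode="edge")
    return np.convolve(xp, np.ones(window) / window, mode="valid")[: x.size]


def _resample_uniform(trace: SensorTrace) -> SensorTrace:
    dt = 1.0 / trace.nominal_rate
    t = np.arange(trace.timestamps[0], trace.timestamps[-1] + dt / 2, dt)
    return SensorTrace(
        trace.channel_name, t, trace.value_at(t), trace.units, trace.nominal_rate
    )


def _zero_crossing_extent(smoothed: np.ndarray, peak_idx: int) -> tuple[int, int]:
    """Indices of the first samples on either side where the smoothed signal
    leaves the peak's sign (zero counts as a crossing)."""
    s = np.sign(smoothed[peak_idx])
    lo = peak_idx
    while lo > 0 and np.sign(smoothed[lo - 1]) == s:
        lo -= 1
    hi = peak_idx
    n = smoothed.size
    while hi < n - 1 and np.sign(smoothed[hi + 1]) == s:
        hi += 1
    return lo, hi


def detect_turns(gyro: SensorTrace, config: TurnConfig | None = None) -> list[TurnEvent]:
    """Detect turn maneuvers in a uniformly sampled angular-velocity trace."""
    config = config or TurnConfig()
    if len(gyro) == 0:
        return []
    if not gyro.is_uniform():
        if not config.resample:
            raise ValueError(
                "gyro trace is not uniformly sampled; set TurnConfig.resample=True"
            )
        gyro = _resample_uniform(gyro)
    t = gyro.timestamps
    raw = gyro.values
    dt = float(t[1] - t[0]) if len(gyro) > 1 else 1.0 / gyro.nominal_rate
    smoothed = _moving_average(raw, config.smooth_window)
    accel = np.gradient(smoothed, t)

    distance = max(1, int(round(config.min_separation_s / dt)))
    peaks, _props = find_peaks(
        np.abs(smoothed), height=config.peak_threshold, distance=distance
    )
    events: list[TurnEvent] = []
    h = config.window_half_width
    for p in peaks:
        lo_w = max(0, p - h)
        hi_w = min(raw.size - 1, p + h)
        # refine the peak on the raw series near the smoothed peak
        lo_r = max(0, p - config.smooth_window)
        hi_r = min(raw.size - 1, p + config.smooth_window)
        p_raw = lo_r + int(np.argmax(np.abs(raw[lo_r : hi_r + 1])))
        peak_omega = float(raw[p_raw])
        sign = 1.0 if peak_omega >= 0 else -1.0

        lo_z, hi_z = _zero_crossing_extent(smoothed, p)
        angle = float(np.trapezoid(raw[lo_z : hi_z + 1], t[lo_z : hi_z + 1]))

        a_win = accel[lo_w : hi_w + 1] * sign  # handedness frame
        kind = _classify(angle, config)
        events.append(
            TurnEvent(
                peak_time=float(t[p_raw]),
                kind=kind,
                peak_angular_velocity=peak_omega,
                max_angular_acceleration=float(np.max(a_win)),
                min_angular_acceleration=float(np.min(a_win)),
                integrated_angle=angle,
                window=(float(t[lo_w]), float(t[hi_w])),
                extent=(float(t[lo_z]), float(t[hi_z])),
            )
        )
    # minor turns inside a detected U-turn's extent are artifacts of the
    # larger maneuver: relabel and exclude them from aggregates
    uturn_spans = [e.extent for e in events if e.kind == "uturn180"]
    for e in events:
        if e.kind != "uturn180" and any(a <= e.peak_time <= b for a, b in uturn_spans):
            e.kind = "minor"
    for e in events:
        if e.kind == "uturn180":
            try:
                e.period = uturn_period(e, gyro, config.period_fraction)
            except ValueError:
                e.period = float("nan")
    return events


def _classify(angle: float, config: TurnConfig) -> str:
    if abs(angle) < config.minor_angle_cutoff:
        return "minor"
    if abs(angle) >= config.uturn_angle_cutoff:
        return "uturn180"
    left = angle > 0 if config.left_positive else angle < 0
    return "left90" if left else "right90"


def speed_at_peaks(turns: Iterable[TurnEvent], gps: GpsTrack) -> list[TurnEvent]:
    """Attach linearly interpolated GPS speed to each event (mph).

    Events whose peak time falls outside the GPS coverage are flagged
    (``speed_valid=False``) and excluded from aggregates.
    """
    out = []
    for e in turns:
        if gps.covers(e.peak_time):
            e.speed_at_peak = float(gps.speed_at(e.peak_time))
            e.speed_valid = True
        else:
            e.speed_at_peak = float("nan")
            e.speed_valid = False
        out.append(e)
    return out


def uturn_period(event: TurnEvent, gyro: SensorTrace, frac: float = 0.1) -> float:
    """Duration of a 180-degree turn: the time spent above ``frac`` of the
    peak angular velocity (between the last upward and first downward
    crossings of the level around the peak), with sub-sample interpolation."""
    if event.kind != "uturn180":
        raise ValueError("period is defined for uturn180 events")
    if not 0.0 < frac < 1.0:
        raise ValueError("frac must be in (0, 1)")
    t = gyro.timestamps
    y = np.abs(gyro.values)
    p = int(np.argmin(np.abs(t - event.peak_time)))
    level = frac * abs(event.peak_angular_velocity)
    lo = p
    while lo > 0 and y[lo - 1] >= level:
        lo -= 1
    hi = p
    while hi < y.size - 1 and y[hi + 1] >= level:
        hi += 1
    if lo == 0 or hi == y.size - 1:
        raise ValueError("U-turn truncated: crossings not found within the trace")
    # linear interpolation to the crossing instants
    t_lo = np.interp(level, [y[lo - 1], y[lo]], [t[lo - 1], t[lo]])
    t_hi = np.interp(level, [y[hi + 1], y[hi]], [t[hi + 1], t[hi]])
    return float(t_hi - t_lo)


_SIGNATURE_FIELDS = (
    "left90_max_angular_velocity",
    "right90_max_angular_velocity",
    "combined90_max_angular_velocity",
    "left90_max_angular_acceleration",
    "right90_max_angular_acceleration",
    "combined90_max_angular_acceleration",
    "left90_min_angular_acceleration",
    "right90_min_angular_acceleration",
    "combined90_min_angular_acceleration",
    "left90_speed_at_peak",
    "right90_speed_at_peak",
    "combined90_speed_at_peak",
    "uturn_period",
    "uturn_speed_at_peak",
    "uturn_max_angular_velocity",
    "uturn_max_angular_acceleration",
)


@dataclass
class SignatureSet:
    """The 16 session-level driving-performance signatures.

    Angular velocities are magnitudes (rad/s); accelerations are in the
    turn's handedness frame (rad/s^2); speeds in mph; the U-turn period in
    seconds.  A signature is ``None`` when no qualifying events exist.
    """

    left90_max_angular_velocity: float | None = None
    right90_max_angular_velocity: float | None = None
    combined90_max_angular_velocity: float | None = None
    left90_max_angular_acceleration: float | None = None
    right90_max_angular_acceleration: float | None = None
    combined90_max_angular_acceleration: float | None = None
    left90_min_angular_acceleration: float | None = None
    right90_min_angular_acceleration: float | None = None
    combined90_min_angular_acceleration: float | None = None
    left90_speed_at_peak: float | None = None
    right90_speed_at_peak: float | None = None
    combined90_speed_at_peak: float | None = None
    uturn_period: float | None = None
    uturn_speed_at_peak: float | None = None
    uturn_max_angular_velocity: float | None = None
    uturn_max_angular_acceleration: float | None = None
    n_events: dict = field(default_factory=dict)

    def as_dict(self) -> dict[str, float | None]:
        return {f: getattr(self, f) for f in _SIGNATURE_FIELDS}


def _mean(vals: list[float]) -> float | None:
    vals = [v for v in vals if not math.isnan(v)]
    return float(np.mean(vals)) if vals else None


def _combine(left: float | None, right: float | None) -> float | None:
    present = [v for v in (left, right) if v is not None]
    return float(np.mean(present)) if present else None


def aggregate_signatures(turns: Iterable[TurnEvent]) -> SignatureSet:
    """Session-level signature means over non-minor events.

    Combined 90-degree values are the mean of the left-only and right-only
    means (the two sides carry equal weight even though the circuit has four
    left and three right turns per lap); with only one side present the
    combined value equals that side's value.  Events with invalid speed are
    excluded from speed signatures only.
    """
    by_kind: dict[str, list[TurnEvent]] = {"left90": [], "right90": [], "uturn180": []}
    for e in turns:
        if e.kind in by_kind:
            by_kind[e.kind].append(e)
    sig = SignatureSet()
    sig.n_events = {k: len(v) for k, v in by_kind.items()}

    def side(kind, metric):
        ev = by_kind[kind]
        if metric == "speed":
            vals = [e.speed_at_peak for e in ev if e.speed_valid]
        elif metric == "peak":
            vals = [abs(e.peak_angular_velocity) for e in ev]
        elif metric == "amax":
            vals = [e.max_angular_acceleration for e in ev]
        elif metric == "amin":
            vals = [e.min_angular_acceleration for e in ev]
        elif metric == "period":
            vals = [e.period for e in ev]
        else:
            raise KeyError(metric)
        return _mean(vals)

    sig.left90_max_angular_velocity = side("left90", "peak")
    sig.right90_max_angular_velocity = side("right90", "peak")
    sig.combined90_max_angular_velocity = _combine(
        sig.left90_max_angular_velocity, sig.right90_max_angular_velocity
    )
    sig.left90_max_angular_acceleration = side("left90", "amax")
    sig.right90_max_angular_acceleration = side("right90", "amax")
    sig.combined90_max_angular_acceleration = _combine(
        sig.left90_max_angular_acceleration, sig.right90_max_angular_acceleration
    )
    sig.left90_min_angular_acceleration = side("left90", "amin")
    sig.right90_min_angular_acceleration = side("right90", "amin")
    sig.combined90_min_angular_acceleration = _combine(
        sig.left90_min_angular_acceleration, sig.right90_min_angular_acceleration
    )
    sig.left90_speed_at_peak = side("left90", "speed")
    sig.right90_speed_at_peak = side("right90", "speed")
    sig.combined90_speed_at_peak = _combine(
        sig.left90_speed_at_peak, sig.right90_speed_at_peak
    )
    sig.uturn_period = side("uturn180", "period")
    sig.uturn_speed_at_peak = side("uturn180", "speed")
    sig.uturn_max_angular_velocity = side("uturn180", "peak")
    sig.uturn_max_angular_acceleration = side("uturn180", "amax")
    return sig
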