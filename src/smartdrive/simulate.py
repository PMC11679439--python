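"""Synthetic standardized-test sessions: kinematics, cabin CO2, cohorts.

This module replaces the in-vehicle hardware and the study cohort with a
parameterized simulator so every downstream stage (turn detection, metabolic
fitting, path scoring, classification) can be exercised end to end.

A session is the three-phase protocol: parked (baseline accumulation),
normal driving (10 laps of the 540 m circuit at 8-12 mph), aggressive
driving (10 laps at 15-21 mph), in that fixed order.  The simulator produces
the gyroscope z channel at 10 Hz, GPS fixes at 1 Hz, cabin CO2 integrated
against the speed-dependent air-exchange model with the hysteresis
ventilation controller in the loop, and slowly varying cabin temperature,
humidity and pressure channels.

Driver cognition enters through two families of parameters, chosen to mirror
the qualitative group separation the device is designed to pick up:

* the fractional EE rise from normal to aggressive driving is >= 16 % for
  normal-cognition profiles and below 16 % for MCI profiles;
* path-discrepancy events (missed / unplanned / consecutive U-turns,
  off-path and exited-path excursions) occur at positive Poisson rates only
  for MCI profiles.

Injected events are recorded in a ground-truth ledger so detector output can
be scored exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.integrate import cumulative_trapezoid
from shapely.geometry import LineString, Point

from . import metabolic
from .circuit import CircuitGeometry, Maneuver
from .traces import (
    DesignatedPath,
    GpsTrack,
    Phase,
    SensorTrace,
    SessionDescriptor,
    mph_to_mps,
    write_gps_csv,
    write_path_geojson,
    write_session,
    write_trace_csv,
)
from .ventilation import PURGING, VentController

__all__ = [
    "NoiseConfig",
    "DriverProfile",
    "CabinEnvironment",
    "DriveKinematics",
    "InjectedEvent",
    "SimulatedSubject",
    "CohortConfig",
    "simulate_kinematics",
    "designated_path_from_kinematics",
    "sample_error_counts",
    "inject_path_errors",
    "simulate_cabin_co2",
    "simulate_subject",
    "generate_cohort",
]

GYRO_RATE_HZ = 10.0
GPS_RATE_HZ = 1.0
FINE_DT = 0.02  # integration step for positions; divides both sample grids

ERROR_CRITERIA = (
    "uturns_missed",
    "uturns_unplanned",
    "uturns_consecutive",
    "off_path",
    "exited_path",
)

#: perimeter of the parking lot: buffer of the designated polyline (m)
PERIMETER_BUFFER_M = 15.0
#: radius of the planned U-turn zones (m), centered on the U-turn arc apex;
#: small enough that passes along the adjacent straights stay outside
UTURN_ZONE_RADIUS_M = 5.0


@dataclass
class NoiseConfig:
    """Measurement-noise levels; all independent Gaussian unless noted."""

    gyro_sd: float = 0.05  # rad/s, additive
    gps_sd_m: float = 1.0  # per-axis position noise = GPS fix error
    speed_sd_mph: float = 0.2
    co2_frac_sd: float = 0.01  # multiplicative CO2 measurement noise
    env_temp_sd: float = 0.1  # degC
    env_rh_sd: float = 0.5  # % RH
    env_pbar_sd: float = 0.2  # mmHg

    @classmethod
    def none(cls) -> "NoiseConfig":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


def _default_path_rates() -> dict[str, float]:
    return {k: 0.0 for k in ERROR_CRITERIA}


@dataclass
class DriverProfile:
    """Behavioural and physiological parameters of one simulated driver.

    ``ee_gain_normal`` is the fractional EE increase from parked to normal
    driving; ``ee_gain_aggressive`` is the fractional increase from normal
    to aggressive driving (so it is directly the EE-change indicator the
    analysis recovers).
    """

    cognition: str = "normal"  # 'normal' | 'mci'
    base_ee: float = 1400.0  # parked-phase EE, kcal/day
    ee_gain_normal: float = 0.10
    ee_gain_aggressive: float = 0.25
    speed_normal_mph: float = 10.0  # protocol range 8-12
    speed_aggressive_mph: float = 18.0  # protocol range 15-21
    turn_sharpness: float = 1.0  # >1 shortens turns, raising peak angular velocity
    path_error_rates: dict[str, float] = field(default_factory=_default_path_rates)
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.cognition not in ("normal", "mci"):
            raise ValueError("cognition must be 'normal' or 'mci'")
        if self.ee_gain_normal < 0 or self.base_ee <= 0:
            raise ValueError("EE parameters must be positive")
        if any(v < 0 for v in self.path_error_rates.values()):
            raise ValueError("path error rates must be >= 0")
        unknown = set(self.path_error_rates) - set(ERROR_CRITERIA)
        if unknown:
            raise ValueError(f"unknown path error criteria: {sorted(unknown)}")

    def phase_speed(self, phase: str) -> float:
        if phase == "normal":
            return self.speed_normal_mph
        if phase == "aggressive":
            return self.speed_aggressive_mph
        raise ValueError(f"no driving speed for phase {phase!r}")

    def phase_ee(self, phase: str) -> float:
        if phase == "parked":
            return self.base_ee
        if phase == "normal":
            return self.base_ee * (1.0 + self.ee_gain_normal)
        if phase == "aggressive":
            return self.base_ee * (1.0 + self.ee_gain_normal) * (1.0 + self.ee_gain_aggressive)
        raise ValueError(f"unknown phase {phase!r}")


@dataclass
class CabinEnvironment:
    """Mean cabin conditions; channels are these values plus slow noise."""

    temperature_c: float = 25.0
    relative_humidity_pct: float = 30.0
    pressure_mmhg: float = 740.0
    cabin_volume_ml: float = 3.0e6
    rate_hz: float = 0.2

    def stpd_inputs(self) -> metabolic.StpdInputs:
        return metabolic.StpdInputs(
            self.temperature_c, self.pressure_mmhg, self.relative_humidity_pct
        )


@dataclass
class DriveKinematics:
    """Output of one driving phase: sensors plus simulation ground truth."""

    gyro: SensorTrace
    gps: GpsTrack
    schedule: list[Maneuver]
    path_xy: np.ndarray  # noiseless fine-grained trajectory
    speed_mph: float


@dataclass
class InjectedEvent:
    kind: str  # one of ERROR_CRITERIA
    time_s: float
    lap_index: int
    magnitude_m: float = 0.0  # lateral excursion for off/exited events


def _raised_cosine(t, t0, duration, dtheta):
    """Angular-velocity pulse integrating exactly to ``dtheta``."""
    tau = (np.asarray(t, dtype=float) - t0) / duration
    inside = (tau >= 0.0) & (tau <= 1.0)
    return np.where(inside, dtheta / duration * (1.0 - np.cos(2.0 * np.pi * tau)), 0.0)


def _omega_from_schedule(t: np.ndarray, schedule: list[Maneuver]) -> np.ndarray:
    omega = np.zeros_like(t, dtype=float)
    for m in schedule:
        if m.kind == "straight":
            continue
        omega += _raised_cosine(t, m.t_start, m.duration, m.dtheta)
    return omega


def simulate_kinematics(
    profile: DriverProfile,
    geometry: CircuitGeometry,
    phase: str,
    *,
    laps: int | None = None,
    noise: NoiseConfig | None = None,
    seed: int | None = None,
    t_offset: float = 0.0,
    start_pose: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> DriveKinematics:
    """Simulate gyro (10 Hz) and GPS (1 Hz) for one driving phase.

    The vehicle traverses the chained-lap schedule at the profile's phase
    speed; corners are raised-cosine angular-velocity pulses whose integral
    equals the corner angle exactly.  GPS positions are the integrated
    trajectory plus isotropic noise with per-axis sd equal to the fix error;
    deterministic given ``seed``.
    """
    noise = noise or NoiseConfig.none()
    speed_mps = float(mph_to_mps(profile.phase_speed(phase)))
    if not speed_mps > 0:
        raise ValueError("zero speed: cannot traverse the circuit")
    geometry_local = geometry
    if profile.turn_sharpness != 1.0:
        # sharper turns = tighter radii = shorter pulses with higher peaks
        geometry_local = replace(
            geometry,
            corner_radius_m=geometry.corner_radius_m / profile.turn_sharpness,
            uturn_radius_m=geometry.uturn_radius_m / profile.turn_sharpness,
        )
    schedule = geometry_local.schedule(speed_mps, laps=laps, dt_snap=1.0 / GYRO_RATE_HZ)
    t_total = schedule[-1].t_end

    t_fine = np.arange(0.0, t_total + FINE_DT / 2, FINE_DT)
    omega_fine = _omega_from_schedule(t_fine, schedule)
    x0, y0, theta0 = start_pose
    theta = theta0 + cumulative_trapezoid(omega_fine, t_fine, initial=0.0)
    x = x0 + cumulative_trapezoid(speed_mps * np.cos(theta), t_fine, initial=0.0)
    y = y0 + cumulative_trapezoid(speed_mps * np.sin(theta), t_fine, initial=0.0)
    path_xy = np.stack([x, y], axis=1)

    rng = np.random.default_rng(seed)
    # gyroscope at 10 Hz (fine grid is an exact refinement)
    step_g = int(round(1.0 / GYRO_RATE_HZ / FINE_DT))
    t_gyro = t_fine[::step_g]
    w_gyro = omega_fine[::step_g].copy()
    if noise.gyro_sd > 0:
        w_gyro += rng.normal(0.0, noise.gyro_sd, size=w_gyro.size)
    gyro = SensorTrace("gyro_z", t_gyro + t_offset, w_gyro, "rad/s", GYRO_RATE_HZ)

    step_p = int(round(1.0 / GPS_RATE_HZ / FINE_DT))
    t_gps = t_fine[::step_p]
    xy = path_xy[::step_p].copy()
    speed = np.full(t_gps.size, profile.phase_speed(phase))
    if noise.gps_sd_m > 0:
        xy += rng.normal(0.0, noise.gps_sd_m, size=xy.shape)
    if noise.speed_sd_mph > 0:
        speed = np.maximum(0.0, speed + rng.normal(0.0, noise.speed_sd_mph, size=speed.size))
    gps = GpsTrack(t_gps + t_offset, xy, speed, fix_error=max(noise.gps_sd_m, 1.0))

    shifted = [
        Maneuver(m.kind, m.t_start + t_offset, m.t_end + t_offset, m.dtheta, m.lap_index,
                 m.straight_index)
        for m in schedule
    ]
    return DriveKinematics(gyro, gps, shifted, path_xy, profile.phase_speed(phase))


def designated_path_from_kinematics(
    kin: DriveKinematics,
    *,
    vertex_spacing_m: float = 1.0,
    perimeter_buffer_m: float = PERIMETER_BUFFER_M,
    uturn_zone_radius_m: float = UTURN_ZONE_RADIUS_M,
) -> DesignatedPath:
    """Designated path, perimeter and planned U-turn zones from a reference run."""
    xy = kin.path_xy
    d = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(xy, axis=0), axis=1))])
    n_vertices = max(2, int(d[-1] / vertex_spacing_m))
    s = np.linspace(0.0, d[-1], n_vertices)
    verts = np.stack([np.interp(s, d, xy[:, 0]), np.interp(s, d, xy[:, 1])], axis=1)
    perimeter = LineString(verts).buffer(perimeter_buffer_m)
    t0 = kin.gyro.timestamps[0]
    zones = []
    spans = []
    for m in kin.schedule:
        if m.kind != "uturn180":
            continue
        i_mid = int(round((m.t_mid - t0) / FINE_DT))
        i_mid = min(max(i_mid, 0), xy.shape[0] - 1)
        zones.append(Point(xy[i_mid]).buffer(uturn_zone_radius_m))
        i0 = min(max(int(round((m.t_start - t0) / FINE_DT)), 0), d.size - 1)
        i1 = min(max(int(round((m.t_end - t0) / FINE_DT)), 0), d.size - 1)
        spans.append((float(d[i0]), float(d[i1])))
    return DesignatedPath(verts, perimeter, zones, spans)


# ---------------------------------------------------------------------------
# path-discrepancy injection
# ---------------------------------------------------------------------------

# straights flanked by 90-degree turns on both sides: inserting a U-turn there
# can never create a spurious consecutive-U-turn pair with the planned one
_ELIGIBLE_STRAIGHTS = (1, 2, 3, 6, 7)


def _merge_runs(idx: np.ndarray, gap: int) -> list[tuple[int, int]]:
    runs: list[list[int]] = [[int(idx[0]), int(idx[0])]]
    for i in idx[1:]:
        if i - runs[-1][1] < gap:
            runs[-1][1] = int(i)
        else:
            runs.append([int(i), int(i)])
    return [(a, b) for a, b in runs]


def _solve_peak(kind, anchor, dirvec, line, perim_in, perim_out):
    """Smallest lateral offset realizing the intended event on this side."""
    if kind == "off_path":
        for k in np.arange(9.0, 26.0, 1.0):
            p = Point(anchor + k * dirvec)
            if line.distance(p) >= 10.0 and perim_in.covers(p):
                return float(k)
        return None
    for k in np.arange(10.0, 80.0, 2.0):
        p = Point(anchor + k * dirvec)
        if not perim_out.covers(p):
            return float(k + 4.0)
    return None


def _valid_excursion(kind, cand, line, perim_in, perim_out) -> bool:
    """Would the detector see exactly one event of the intended kind?"""
    import shapely as _sh

    pts = _sh.points(cand)
    d = _sh.distance(pts, line)
    idx = np.flatnonzero(d >= 8.0)
    if idx.size == 0:
        return False
    runs = _merge_runs(idx, gap=3)
    if len(runs) != 1:
        return False
    a, b = runs[0]
    seg = pts[a : b + 1]
    if kind == "off_path":
        return bool(np.all(_sh.covers(perim_in, seg)) and float(np.max(d[a : b + 1])) >= 10.0)
    return bool(np.any(~_sh.covers(perim_out, seg)))


def sample_error_counts(
    rates: dict[str, float], rng: np.random.Generator
) -> dict[str, int]:
    """Poisson counts per criterion from expected per-session rates."""
    return {k: int(rng.poisson(rates.get(k, 0.0))) for k in ERROR_CRITERIA}


def inject_path_errors(
    kin: DriveKinematics,
    path: DesignatedPath,
    counts: dict[str, int],
    rng: np.random.Generator,
    *,
    max_retries: int = 50,
) -> tuple[DriveKinematics, list[InjectedEvent]]:
    """Realize sampled path-discrepancy events on one driving phase.

    U-turn criteria are realized on the gyroscope channel (a missed U-turn
    deletes the planned pulse, unplanned/consecutive insert pulses on
    straights), off-path and exited-path as smooth lateral GPS excursions.
    Returns the edited kinematics and the ground-truth ledger.  Raises if a
    geometrically valid placement cannot be found within ``max_retries``.
    """
    gyro_t = kin.gyro.timestamps
    gyro_v = kin.gyro.values.copy()
    xy = kin.gps.xy.copy()
    ledger: list[InjectedEvent] = []

    uturns = [m for m in kin.schedule if m.kind == "uturn180"]
    straights = [
        m for m in kin.schedule if m.kind == "straight" and m.straight_index in _ELIGIBLE_STRAIGHTS
    ]
    used_straights: set[tuple[int, int]] = set()
    used_laps_missed: set[int] = set()

    def pick_straight(min_duration: float) -> Maneuver:
        pool = [
            m
            for m in straights
            if m.duration >= min_duration
            and (m.lap_index, m.straight_index) not in used_straights
        ]
        if not pool:
            raise RuntimeError("could not place path-discrepancy event (too many events?)")
        m = pool[rng.integers(len(pool))]
        used_straights.add((m.lap_index, m.straight_index))
        return m

    # --- missed U-turns: delete the planned pulse from the gyro -------------
    for _ in range(counts.get("uturns_missed", 0)):
        candidates = [m for m in uturns if m.lap_index not in used_laps_missed]
        if not candidates:
            raise RuntimeError("more missed U-turns requested than laps available")
        m = candidates[rng.integers(len(candidates))]
        used_laps_missed.add(m.lap_index)
        mask = (gyro_t >= m.t_start - 0.5) & (gyro_t <= m.t_end + 0.5)
        gyro_v[mask] = 0.0
        ledger.append(InjectedEvent("uturns_missed", m.t_mid, m.lap_index))

    # --- unplanned U-turns: insert a +pi pulse on an eligible straight ------
    # a pulse peak must stay >= min-separation away from the neighbouring
    # corner peaks so the detector treats it as a distinct maneuver
    pulse_dur = 3.0
    for _ in range(counts.get("uturns_unplanned", 0)):
        m = pick_straight(6.0)
        t0 = m.t_mid - pulse_dur / 2.0
        gyro_v += _raised_cosine(gyro_t, t0, pulse_dur, math.pi)
        ledger.append(InjectedEvent("uturns_unplanned", m.t_mid, m.lap_index))

    # --- consecutive U-turns: a there-and-back pair of pulses ---------------
    gap = 1.5
    for _ in range(counts.get("uturns_consecutive", 0)):
        m = pick_straight(10.0)
        t0 = m.t_mid - pulse_dur - gap / 2.0
        gyro_v += _raised_cosine(gyro_t, t0, pulse_dur, math.pi)
        gyro_v += _raised_cosine(gyro_t, t0 + pulse_dur + gap, pulse_dur, -math.pi)
        ledger.append(InjectedEvent("uturns_consecutive", m.t_mid, m.lap_index))

    # --- lateral excursions --------------------------------------------------
    # the chained circuit runs close to itself in places (the out and back
    # corridors of a lap are two turn diameters apart), so a candidate
    # excursion is validated against the actual path geometry before being
    # applied: the realized fixes must reproduce exactly one event of the
    # intended kind under the detector's distance/perimeter rules
    line = path.linestring
    perim_in = path.perimeter.buffer(-3.0)
    perim_out = path.perimeter.buffer(3.0)

    def plan_excursion(kind: str) -> None:
        for _attempt in range(max_retries):
            m = pick_straight(6.0)
            dur = min(10.0, m.duration - 2.0)
            t0, t1 = m.t_mid - dur / 2.0, m.t_mid + dur / 2.0
            tt = kin.gps.timestamps
            idx = np.flatnonzero((tt >= t0) & (tt <= t1))
            if idx.size < 3:
                continue
            i0, i1 = idx[0], idx[-1]
            direction = xy[min(i1 + 1, xy.shape[0] - 1)] - xy[max(i0 - 1, 0)]
            norm = np.linalg.norm(direction)
            if norm == 0:
                continue
            perp = np.array([-direction[1], direction[0]]) / norm
            prof = np.sin(np.pi * (tt[idx] - t0) / dur) ** 2
            anchor = xy[idx[idx.size // 2]]
            for side in rng.permutation([1.0, -1.0]):
                peak = _solve_peak(kind, anchor, side * perp, line, perim_in, perim_out)
                if peak is None:
                    continue
                cand = xy[idx] + side * peak * np.outer(prof, perp)
                if _valid_excursion(kind, cand, line, perim_in, perim_out):
                    xy[idx] = cand
                    ledger.append(
                        InjectedEvent(kind, m.t_mid, m.lap_index, magnitude_m=peak)
                    )
                    return
        raise RuntimeError(f"could not realize a {kind} excursion geometrically")

    for _ in range(counts.get("off_path", 0)):
        plan_excursion("off_path")
    for _ in range(counts.get("exited_path", 0)):
        plan_excursion("exited_path")

    gyro = SensorTrace("gyro_z", gyro_t, gyro_v, "rad/s", kin.gyro.nominal_rate)
    gps = GpsTrack(kin.gps.timestamps, xy, kin.gps.speed_mph, kin.gps.fix_error)
    out = DriveKinematics(gyro, gps, kin.schedule, kin.path_xy, kin.speed_mph)
    return out, ledger


# ---------------------------------------------------------------------------
# cabin CO2
# ---------------------------------------------------------------------------


def simulate_cabin_co2(
    session: SessionDescriptor,
    profile: DriverProfile,
    speed_series: SensorTrace,
    occupants: int,
    vent: VentController | None,
    env: CabinEnvironment,
    constants: metabolic.MetabolicConstants | None = None,
    *,
    rate_hz: float = 1.0,
    co2_initial: float = 550.0,
    purge_multiplier: float = 15.0,
    noise: NoiseConfig | None = None,
    seed: int | None = None,
) -> SensorTrace:
    """Forward-integrate cabin CO2 over the whole session.

    Per sample the state advances by the exact exponential update of the
    first-order balance (so a constant-speed recirculation stretch matches
    the closed-form profile to machine precision).  The generation rate is
    the profile's phase EE (times ``occupants``) inverted through the EE
    chain; the exchange rate follows the speed trendline during
    recirculation and ``purge_multiplier`` times it while the controller
    purges.  The controller sees the measured (noisy) concentration, like
    the real system.
    """
    if occupants < 1:
        raise ValueError("occupants must be >= 1")
    constants = constants or metabolic.MetabolicConstants()
    noise = noise or NoiseConfig.none()
    rng = np.random.default_rng(seed)
    cf_stpd = metabolic.stpd_factor(env.stpd_inputs(), constants)
    kgen_by_phase = {
        p.label: occupants
        * metabolic.kgen_from_ee(
            profile.phase_ee(p.label), session.cabin_volume_ml, cf_stpd, constants
        )
        for p in session.phases
    }

    t0 = session.phases[0].start
    t1 = session.phases[-1].end
    dt = 1.0 / rate_hz
    times = np.arange(t0, t1 + dt / 2, dt)
    c0 = constants.co2_outdoor_ppm
    c = float(co2_initial)
    true_vals = np.empty(times.size)
    meas_vals = np.empty(times.size)

    def phase_at(t: float) -> str | None:
        for p in session.phases:
            if p.start <= t < p.end or (p is session.phases[-1] and t == p.end):
                return p.label
        return None

    state = "recirculating"
    for i, t in enumerate(times):
        if i > 0:
            label = phase_at(times[i - 1])
            k = kgen_by_phase.get(label, 0.0)
            speed = max(0.0, float(speed_series.value_at(times[i - 1])))
            lam = metabolic.lambda_from_speed(speed, constants)
            if state == PURGING:
                lam *= purge_multiplier
            dh = dt / 3600.0
            decay = math.exp(-lam * dh)
            c = c0 + k / lam + (c - c0 - k / lam) * decay
        true_vals[i] = c
        meas = c * (1.0 + rng.normal(0.0, noise.co2_frac_sd)) if noise.co2_frac_sd > 0 else c
        meas_vals[i] = meas
        if vent is not None:
            state = vent.step(meas, float(t))
        else:
            state = "recirculating"
    return SensorTrace("co2", times, meas_vals, "ppm", rate_hz)


# ---------------------------------------------------------------------------
# whole subjects and cohorts
# ---------------------------------------------------------------------------


@dataclass
class SimulatedSubject:
    subject_id: str
    profile: DriverProfile
    session: SessionDescriptor
    kinematics: dict[str, DriveKinematics]  # per driving phase
    co2: SensorTrace
    env_traces: dict[str, SensorTrace]
    environment: CabinEnvironment
    vent_log: list[tuple[float, str]]
    path: DesignatedPath
    ledger: list[InjectedEvent]
    ledger_by_phase: dict[str, list[InjectedEvent]]

    @property
    def label(self) -> str:
        return "normal_cognition" if self.profile.cognition == "normal" else "mci"


def _env_trace(name, mean, sd, units, t0, t1, rate_hz, rng):
    dt = 1.0 / rate_hz
    t = np.arange(t0, t1 + dt / 2, dt)
    v = np.full(t.size, mean) + (rng.normal(0.0, sd, t.size) if sd > 0 else 0.0)
    return SensorTrace(name, t, v, units, rate_hz)


def simulate_subject(
    profile: DriverProfile,
    *,
    subject_id: str = "S000",
    geometry: CircuitGeometry | None = None,
    environment: CabinEnvironment | None = None,
    constants: metabolic.MetabolicConstants | None = None,
    noise: NoiseConfig | None = None,
    parked_duration_s: float = 600.0,
    occupants: int = 1,
    vent_thresholds: tuple[float, float] = (600.0, 900.0),
    seed: int | None = None,
) -> SimulatedSubject:
    """Simulate one complete three-phase standardized session."""
    geometry = geometry or CircuitGeometry()
    environment = environment or CabinEnvironment()
    constants = constants or metabolic.MetabolicConstants()
    noise = noise if noise is not None else NoiseConfig()
    if profile.rng_seed is not None and seed is None:
        seed = profile.rng_seed
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(8) % (2**31)

    # reference noiseless run defines the designated path and U-turn zones
    ref = simulate_kinematics(
        profile, geometry, "normal", noise=NoiseConfig.none(), seed=0
    )
    path = designated_path_from_kinematics(ref)

    kinematics: dict[str, DriveKinematics] = {}
    ledger: list[InjectedEvent] = []
    ledger_by_phase: dict[str, list[InjectedEvent]] = {}
    t_cursor = parked_duration_s
    phases = [Phase("parked", 0.0, parked_duration_s)]
    rng_counts = np.random.default_rng(int(seeds[0]))
    counts = sample_error_counts(profile.path_error_rates, rng_counts)
    # split sampled events between the two driving phases
    counts_by_phase = {"normal": dict.fromkeys(ERROR_CRITERIA, 0),
                       "aggressive": dict.fromkeys(ERROR_CRITERIA, 0)}
    for k, n in counts.items():
        for _ in range(n):
            ph = "normal" if rng_counts.random() < 0.5 else "aggressive"
            counts_by_phase[ph][k] += 1

    for j, phase_label in enumerate(("normal", "aggressive")):
        kin = simulate_kinematics(
            profile,
            geometry,
            phase_label,
            noise=noise,
            seed=int(seeds[1 + j]),
            t_offset=t_cursor,
        )
        rng_inject = np.random.default_rng(int(seeds[3 + j]))
        kin, events = inject_path_errors(kin, path, counts_by_phase[phase_label], rng_inject)
        kinematics[phase_label] = kin
        ledger_by_phase[phase_label] = events
        ledger.extend(events)
        t_end = kin.gyro.timestamps[-1]
        phases.append(Phase(phase_label, t_cursor, float(t_end)))
        t_cursor = float(t_end) + 5.0  # short gap between phases

    session = SessionDescriptor(
        subject_id=subject_id,
        phases=phases,
        cabin_volume_ml=environment.cabin_volume_ml,
        vent_co2_min_ppm=vent_thresholds[0],
        vent_co2_max_ppm=vent_thresholds[1],
        lap_count=geometry.lap_count,
        lap_length_m=geometry.lap_length_m,
    )

    # session-wide speed series (0 while parked) at 1 Hz
    t_all = np.arange(0.0, session.phases[-1].end + 0.5, 1.0)
    speed_all = np.zeros(t_all.size)
    for phase_label, kin in kinematics.items():
        p = session.phase(phase_label)
        m = (t_all >= p.start) & (t_all <= p.end)
        speed_all[m] = kin.gps.speed_at(t_all[m])
    speed_series = SensorTrace("speed", t_all, speed_all, "mph", 1.0)

    vent = VentController(*vent_thresholds)
    co2 = simulate_cabin_co2(
        session,
        profile,
        speed_series,
        occupants,
        vent,
        environment,
        constants,
        noise=noise,
        seed=int(seeds[5]),
    )
    rng_env = np.random.default_rng(int(seeds[6]))
    env_traces = {
        "temperature": _env_trace(
            "temperature", environment.temperature_c, noise.env_temp_sd, "degC",
            0.0, session.phases[-1].end, environment.rate_hz, rng_env
        ),
        "humidity": _env_trace(
            "humidity", environment.relative_humidity_pct, noise.env_rh_sd, "%",
            0.0, session.phases[-1].end, environment.rate_hz, rng_env
        ),
        "pressure": _env_trace(
            "pressure", environment.pressure_mmhg, noise.env_pbar_sd, "mmHg",
            0.0, session.phases[-1].end, environment.rate_hz, rng_env
        ),
    }
    return SimulatedSubject(
        subject_id=subject_id,
        profile=profile,
        session=session,
        kinematics=kinematics,
        co2=co2,
        env_traces=env_traces,
        environment=environment,
        vent_log=list(vent.actuation_log),
        path=path,
        ledger=ledger,
        ledger_by_phase=ledger_by_phase,
    )


def _default_mci_rates() -> dict[str, float]:
    return {
        "uturns_missed": 0.6,
        "uturns_unplanned": 0.7,
        "uturns_consecutive": 0.4,
        "off_path": 1.2,
        "exited_path": 0.4,
    }


@dataclass
class CohortConfig:
    """Group-level parameter distributions for synthetic cohorts.

    Normal-cognition drivers raise their EE by >= 16 % from normal to
    aggressive driving and essentially never stray from the path; MCI
    drivers show a blunted EE response (< 16 %) and positive
    path-discrepancy rates.
    """

    base_ee_mean: float = 1400.0
    base_ee_sd: float = 150.0
    ee_gain_normal_mean: float = 0.10
    ee_gain_normal_sd: float = 0.03
    normal_ee_gain_aggressive: tuple[float, float] = (0.25, 0.06)  # truncated >= 0.16
    mci_ee_gain_aggressive: tuple[float, float] = (0.08, 0.05)  # truncated < 0.16
    speed_normal_range: tuple[float, float] = (8.0, 12.0)
    speed_aggressive_range: tuple[float, float] = (15.0, 21.0)
    mci_path_rates: dict[str, float] = field(default_factory=_default_mci_rates)
    normal_path_rates: dict[str, float] = field(default_factory=_default_path_rates)
    parked_duration_s: float = 600.0
    occupants: int = 1
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    geometry: CircuitGeometry = field(default_factory=CircuitGeometry)
    environment: CabinEnvironment = field(default_factory=CabinEnvironment)


def _truncated_normal(rng, mean, sd, low=-np.inf, high=np.inf, max_tries=1000):
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if low <= x < high or (x == high == np.inf):
            return float(x)
        if low <= x <= high:
            return float(x)
    raise RuntimeError("truncated normal sampling failed")


def sample_profile(cognition: str, config: CohortConfig, rng: np.random.Generator) -> DriverProfile:
    if cognition == "normal":
        gain_mean, gain_sd = config.normal_ee_gain_aggressive
        gain = _truncated_normal(rng, gain_mean, gain_sd, low=0.16)
        rates = dict(config.normal_path_rates)
    else:
        gain_mean, gain_sd = config.mci_ee_gain_aggressive
        gain = _truncated_normal(rng, gain_mean, gain_sd, low=0.0, high=0.159)
        rates = dict(config.mci_path_rates)
    return DriverProfile(
        cognition=cognition,
        base_ee=_truncated_normal(rng, config.base_ee_mean, config.base_ee_sd, low=800.0),
        ee_gain_normal=_truncated_normal(
            rng, config.ee_gain_normal_mean, config.ee_gain_normal_sd, low=0.0
        ),
        ee_gain_aggressive=gain,
        speed_normal_mph=float(rng.uniform(*config.speed_normal_range)),
        speed_aggressive_mph=float(rng.uniform(*config.speed_aggressive_range)),
        path_error_rates=rates,
    )


def generate_cohort(
    n_normal: int,
    n_mci: int,
    config: CohortConfig | None = None,
    seed: int | None = None,
    out_dir: str | Path | None = None,
) -> tuple[list[SimulatedSubject], "object"]:
    """Simulate a cohort; optionally write per-subject trace files.

    Returns the subjects and a pandas manifest (subject_id, label, profile
    parameters).  Deterministic given ``seed``.
    """
    import pandas as pd

    config = config or CohortConfig()
    ss = np.random.SeedSequence(seed)
    n_total = n_normal + n_mci
    child = ss.generate_state(2 * max(n_total, 1) + 1) % (2**31)
    subjects: list[SimulatedSubject] = []
    rows = []
    labels = ["normal"] * n_normal + ["mci"] * n_mci
    for i, cognition in enumerate(labels):
        rng = np.random.default_rng(int(child[2 * i]))
        profile = sample_profile(cognition, config, rng)
        sid = f"S{i:03d}"
        subj = simulate_subject(
            profile,
            subject_id=sid,
            geometry=config.geometry,
            environment=config.environment,
            noise=config.noise,
            parked_duration_s=config.parked_duration_s,
            occupants=config.occupants,
            seed=int(child[2 * i + 1]),
        )
        subjects.append(subj)
        rows.append(
            {
                "subject_id": sid,
                "cognition": cognition,
                "base_ee": profile.base_ee,
                "ee_gain_normal": profile.ee_gain_normal,
                "ee_gain_aggressive": profile.ee_gain_aggressive,
                "speed_normal_mph": profile.speed_normal_mph,
                "speed_aggressive_mph": profile.speed_aggressive_mph,
                "n_injected_events": len(subj.ledger),
            }
        )
    manifest = pd.DataFrame(
        rows,
        columns=[
            "subject_id", "cognition", "base_ee", "ee_gain_normal",
            "ee_gain_aggressive", "speed_normal_mph", "speed_aggressive_mph",
            "n_injected_events",
        ],
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for subj in subjects:
            d = out_dir / subj.subject_id
            d.mkdir(exist_ok=True)
            for phase, kin in subj.kinematics.items():
                write_trace_csv(kin.gyro, d / f"gyro_{phase}.csv")
                write_gps_csv(kin.gps, d / f"gps_{phase}.csv")
            write_trace_csv(subj.co2, d / "co2.csv")
            for name, tr in subj.env_traces.items():
                write_trace_csv(tr, d / f"{name}.csv")
            write_session(subj.session, d / "session.json")
            write_path_geojson(subj.path, d / "path.geojson")
            with open(d / "vent_log.json", "w", encoding="utf-8") as fh:
                json.dump(subj.vent_log, fh)
            with open(d / "ground_truth.json", "w", encoding="utf-8") as fh:
                json.dump(
                    [
                        {"kind": e.kind, "time_s": e.time_s, "lap": e.lap_index,
                         "magnitude_m": e.magnitude_m}
                        for e in subj.ledger
                    ],
                    fh,
                )
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return subjects, manifest
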