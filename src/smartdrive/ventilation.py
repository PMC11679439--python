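"""Cabin ventilation control and CO2-based occupancy estimation.

The controller is a two-threshold hysteresis switch on cabin CO2: when the
concentration reaches the user-set maximum, the fresh-air inlet opens
("purging"); when it falls back to the minimum, the cabin returns to
recirculation.  The same controller object drives both the simulator and the
analysis of recorded actuation logs.

Occupancy is inferred from the CO2 generation rate: the total generation
fitted on recirculation accumulation segments is divided by a nominal
per-person rate and rounded.  Actuation frequency and the mean CO2 slope are
reported as corroborating diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import metabolic
from .traces import SensorTrace, SessionDescriptor

__all__ = [
    "VentController",
    "step_controller",
    "recirculation_intervals",
    "OccupancyEstimate",
    "nominal_per_person_kgen",
    "estimate_occupants",
]

RECIRCULATING = "recirculating"
PURGING = "purging"


@dataclass
class VentController:
    """Two-threshold hysteresis controller on cabin CO2.

    ``actuation_log`` records every state transition as ``(time s, new state)``;
    states in the log strictly alternate by construction.
    """

    co2_min_ppm: float = 600.0
    co2_max_ppm: float = 900.0
    state: str = RECIRCULATING
    enabled: bool = True
    actuation_log: list[tuple[float, str]] = field(default_factory=list)
    _last_t: float = field(default=-np.inf, repr=False)

    def __post_init__(self) -> None:
        if not self.co2_min_ppm < self.co2_max_ppm:
            raise ValueError("co2_min must be < co2_max")

    def step(self, co2_now: float, t: float) -> str:
        """Advance the controller one sample; returns the state at time ``t``."""
        if t <= self._last_t:
            raise ValueError(f"controller time must increase (got {t} after {self._last_t})")
        self._last_t = t
        if not self.enabled:
            return self.state
        if self.state == RECIRCULATING and co2_now >= self.co2_max_ppm:
            self.state = PURGING
            self.actuation_log.append((t, PURGING))
        elif self.state == PURGING and co2_now <= self.co2_min_ppm:
            self.state = RECIRCULATING
            self.actuation_log.append((t, RECIRCULATING))
        return self.state

    def reset(self) -> None:
        self.state = RECIRCULATING
        self.actuation_log = []
        self._last_t = -np.inf


def step_controller(controller: VentController, co2_now: float, t: float) -> VentController:
    """Functional wrapper around :meth:`VentController.step`."""
    controller.step(co2_now, t)
    return controller


def recirculation_intervals(
    actuation_log: list[tuple[float, str]], t_start: float, t_end: float
) -> list[tuple[float, float]]:
    """Intervals of ``[t_start, t_end]`` during which the cabin recirculates.

    The controller is assumed to start in recirculation at ``t_start`` unless
    the log says otherwise.
    """
    events = sorted(e for e in actuation_log if t_start <= e[0] <= t_end)
    # state at t_start: last transition before it, else recirculating
    state = RECIRCULATING
    for t, s in sorted(actuation_log):
        if t <= t_start:
            state = s
    out: list[tuple[float, float]] = []
    cur = t_start if state == RECIRCULATING else None
    for t, s in events:
        if s == PURGING and cur is not None:
            if t > cur:
                out.append((cur, t))
            cur = None
        elif s == RECIRCULATING and cur is None:
            cur = t
    if cur is not None and t_end > cur:
        out.append((cur, t_end))
    return out


@dataclass
class OccupancyEstimate:
    occupants: int
    k_gen_total: float  # ppm/hour over recirculation segments
    per_person_kgen: float
    actuations_per_hour: float
    mean_co2_slope_ppm_per_hour: float
    n_segments: int


def nominal_per_person_kgen(
    session: SessionDescriptor,
    constants: "metabolic.MetabolicConstants | None" = None,
    stpd: float = 1.0,
    per_person_ee: float = 1700.0,
) -> float:
    """Generation rate (ppm/hour) implied by one adult at ``per_person_ee``.

    Default is the rate a 1700 kcal/day adult produces in the configured
    cabin, inverting the energy-expenditure chain at the given STPD factor.
    """
    constants = constants or metabolic.MetabolicConstants()
    return metabolic.kgen_from_ee(per_person_ee, session.cabin_volume_ml, stpd, constants)


def estimate_occupants(
    co2: SensorTrace,
    actuation_log: list[tuple[float, str]],
    session: SessionDescriptor,
    constants: "metabolic.MetabolicConstants | None" = None,
    per_person_kgen: float | None = None,
    speed_mph: SensorTrace | None = None,
) -> OccupancyEstimate:
    """Estimate the number of cabin occupants from the CO2 trace.

    Fits the total CO2 generation rate on recirculation accumulation
    segments (duration-weighted mean over segments) and divides by the
    nominal per-person rate; the result is rounded and clamped to >= 1.
    """
    constants = constants or metabolic.MetabolicConstants()
    if per_person_kgen is None:
        per_person_kgen = nominal_per_person_kgen(session, constants)
    segments = metabolic.extract_accumulation_segments(co2, actuation_log, session)
    if not segments:
        raise ValueError("no accumulation segments available for occupancy estimation")
    k_vals, weights, slopes = [], [], []
    for _phase, seg in segments:
        if speed_mph is not None:
            mean_speed = float(np.mean(speed_mph.value_at(seg.timestamps)))
        else:
            mean_speed = 0.0
        lam = metabolic.lambda_from_speed(mean_speed, constants)
        fit = metabolic.fit_kgen(seg, lam, constants.co2_outdoor_ppm)
        k_vals.append(fit.k_gen)
        weights.append(seg.duration)
        if seg.duration > 0:
            slopes.append(3600.0 * (seg.values[-1] - seg.values[0]) / seg.duration)
    k_total = float(np.average(k_vals, weights=weights))
    duration_hr = co2.duration / 3600.0
    n_act = sum(1 for _t, s in actuation_log if s == PURGING)
    occupants = max(1, round(k_total / per_person_kgen))
    return OccupancyEstimate(
        occupants=occupants,
        k_gen_total=k_total,
        per_person_kgen=float(per_person_kgen),
        actuations_per_hour=n_act / duration_hr if duration_hr > 0 else 0.0,
        mean_co2_slope_ppm_per_hour=float(np.mean(slopes)) if slopes else 0.0,
        n_segments=len(segments),
    )
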