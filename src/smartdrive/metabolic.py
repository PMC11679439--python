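"""Metabolic-rate estimation from cabin CO2 accumulation.

While the cabin recirculates, the driver's exhaled CO2 accumulates against a
first-order air-exchange leak.  The concentration follows

    C(t) = C0 + (k_gen / lambda) * (1 - exp(-lambda t)) + (Ci - C0) * exp(-lambda t)

with C0 the outdoor concentration (ppm), Ci the concentration at the start
of the accumulation segment, k_gen the cabin generation rate (ppm/hour) and
lambda the air-exchange rate (1/hour).  The exchange rate grows with vehicle
speed along the calibrated trendline

    lambda(speed) = 0.2534 * speed_mph + 10.323 .

Fitting (k_gen, Ci) on a rising segment with lambda held fixed yields the
generation rate, which converts to the driver's CO2 production VCO2 and then
to energy expenditure EE through a fixed-RQ Weir combination:

    k_gen' = k_gen * CF_env                      (bias correction, 1.143)
    VCO2 [mL/min] = k_gen' * 1e-6 * V_cabin [mL] * CF_STPD / 60
    EE = 3.941 * VCO2 / RQ + 1.106 * VCO2        (RQ = 0.85)

Note the ppm -> volume-fraction conversion (1e-6) is applied explicitly so
VCO2 lands in mL/min.  The classic Weir expression carries an additional
1.44 minutes-to-day factor; the default here omits it to match the
simplified form above (``include_144_factor`` restores it).  CF_STPD is the
standard-temperature-pressure-dry correction computed from cabin
temperature, humidity (via Antoine's vapor-pressure equation) and
barometric pressure.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .traces import SensorTrace, SessionDescriptor
from . import ventilation as _vent_mod  # noqa: F401  (interval helper used below)

__all__ = [
    "MetabolicConstants",
    "StpdInputs",
    "Co2ModelParams",
    "Co2FitResult",
    "MetabolicEstimate",
    "HybridIndicators",
    "EE_CHANGE_THRESHOLD_PCT",
    "SPEED_EE_THRESHOLD",
    "lambda_from_speed",
    "antoine_p_h2o",
    "stpd_factor",
    "co2_closed_form",
    "fit_kgen",
    "extract_accumulation_segments",
    "ee_from_kgen",
    "kgen_from_ee",
    "phase_ee_change",
    "hybrid_indicators",
    "weir_ee",
    "vco2_from_ee",
]

#: Diagnostic threshold on the normal->aggressive EE change (percent).
EE_CHANGE_THRESHOLD_PCT = 16.0
#: Diagnostic threshold on the speed x EE-change hybrid indicator (mph * %).
SPEED_EE_THRESHOLD = 160.0


@dataclass
class MetabolicConstants:
    """Calibration constants of the CO2 -> EE chain."""

    cf_env: float = 1.143  # empirical bias correction on k_gen
    rq: float = 0.85  # respiratory quotient VCO2/VO2
    weir_a: float = 3.941  # kcal per L O2 term
    weir_b: float = 1.106  # kcal per L CO2 term
    lambda_slope: float = 0.2534  # 1/hour per mph
    lambda_intercept: float = 10.323  # 1/hour at standstill
    co2_outdoor_ppm: float = 450.0
    include_144_factor: bool = False  # restore the minutes->day Weir factor
    cf_env_divide: bool = False  # read the bias correction as division
    # Antoine constants for water, mmHg / degC, valid 1-100 degC
    antoine_a: float = 8.07131
    antoine_b: float = 1730.63
    antoine_c: float = 233.426

    def __post_init__(self) -> None:
        if not (0.6 < self.rq < 1.3):
            raise ValueError("RQ outside the physiological range (0.6, 1.3)")
        for name in ("cf_env", "weir_a", "weir_b", "lambda_slope", "lambda_intercept"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def weir_slope(self) -> float:
        """EE per unit VCO2 at the configured RQ."""
        s = self.weir_a / self.rq + self.weir_b
        return s * 1.44 if self.include_144_factor else s

    def kgen_prime(self, k_gen: float) -> float:
        return k_gen / self.cf_env if self.cf_env_divide else k_gen * self.cf_env

    def kgen_from_prime(self, k_gen_prime: float) -> float:
        return k_gen_prime * self.cf_env if self.cf_env_divide else k_gen_prime / self.cf_env


@dataclass
class StpdInputs:
    """Cabin conditions entering the STPD correction."""

    temperature_c: float
    pressure_mmhg: float
    relative_humidity_pct: float

    def __post_init__(self) -> None:
        if self.temperature_c <= -273.0:
            raise ValueError("temperature below absolute zero")
        if not self.pressure_mmhg > 0:
            raise ValueError("pressure must be positive")
        if not 0.0 <= self.relative_humidity_pct <= 100.0:
            raise ValueError("relative humidity must be within [0, 100] %")


@dataclass
class Co2ModelParams:
    co2_outdoor: float  # ppm
    co2_initial: float  # ppm
    k_gen: float  # ppm/hour
    lambda_acc: float  # 1/hour

    def __post_init__(self) -> None:
        if self.k_gen < 0:
            raise ValueError("k_gen must be >= 0")
        if not self.lambda_acc > 0:
            raise ValueError("lambda_acc must be > 0")
        if self.co2_initial < 0:
            raise ValueError("co2_initial must be >= 0")


@dataclass
class Co2FitResult:
    params: Co2ModelParams
    rmse_ppm: float
    n_samples: int
    clipped: bool = False  # fitted k_gen < 0 clipped to 0

    @property
    def k_gen(self) -> float:
        return self.params.k_gen


@dataclass
class MetabolicEstimate:
    phase: str
    k_gen: float  # ppm/hour
    k_gen_prime: float  # ppm/hour
    vco2: float  # mL/min
    vo2: float  # mL/min
    ee: float  # kcal/day
    fit_rmse: float  # ppm
    segment: tuple[float, float]  # (start s, end s)


@dataclass
class HybridIndicators:
    ee_change_pct: float | None = None  # normal -> aggressive
    ee_change_parked_to_normal_pct: float | None = None
    ee_change_parked_to_aggressive_pct: float | None = None
    speed_x_ee: float | None = None  # mph * %
    eq_feature: float | None = None  # composite with path deviation
    path_deviation: float | None = None


# ---------------------------------------------------------------------------
# scalar pieces
# ---------------------------------------------------------------------------


def lambda_from_speed(speed_mph, constants: MetabolicConstants | None = None):
    """Air-exchange rate (1/hour) at the given vehicle speed (mph)."""
    constants = constants or MetabolicConstants()
    speed = np.asarray(speed_mph, dtype=float)
    if np.any(speed < 0):
        raise ValueError("speed must be >= 0")
    out = constants.lambda_slope * speed + constants.lambda_intercept
    return float(out) if out.ndim == 0 else out


def antoine_p_h2o(temperature_c: float, constants: MetabolicConstants | None = None) -> float:
    """Saturation vapor pressure of water (mmHg) from Antoine's equation."""
    c = constants or MetabolicConstants()
    return 10.0 ** (c.antoine_a - c.antoine_b / (c.antoine_c + temperature_c))


def stpd_factor(inputs: StpdInputs, constants: MetabolicConstants | None = None) -> float:
    """Standard temperature, pressure, dry correction factor.

    CF_STPD = (P_bar - P_H2O) / 760 * 273 / (T + 273), with the water partial
    pressure P_H2O = RH/100 * Psat(T) from Antoine's equation.
    """
    p_h2o = inputs.relative_humidity_pct / 100.0 * antoine_p_h2o(
        inputs.temperature_c, constants
    )
    if p_h2o > inputs.pressure_mmhg:
        raise ValueError("water partial pressure exceeds barometric pressure")
    return (
        (inputs.pressure_mmhg - p_h2o) / 760.0 * 273.0 / (inputs.temperature_c + 273.0)
    )


def co2_closed_form(t_seconds, co2_outdoor, co2_initial, k_gen, lambda_acc):
    """Closed-form accumulation profile; ``t_seconds`` relative to segment start."""
    t_hr = np.asarray(t_seconds, dtype=float) / 3600.0
    decay = np.exp(-lambda_acc * t_hr)
    return (
        co2_outdoor
        + k_gen / lambda_acc * (1.0 - decay)
        + (co2_initial - co2_outdoor) * decay
    )


# ---------------------------------------------------------------------------
# segment extraction and fitting
# ---------------------------------------------------------------------------


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or x.size < window:
        return x.astype(float)
    kernel = np.ones(window) / window
    pad = window // 2
    xp = np.pad(x.astype(float), pad, mode="edge")
    return np.convolve(xp, kernel, mode="valid")[: x.size]


def extract_accumulation_segments(
    co2: SensorTrace,
    actuation_log: list[tuple[float, str]] | None,
    session: SessionDescriptor,
    *,
    min_duration_s: float = 120.0,
    smooth_window_s: float = 31.0,
    slope_tolerance_ppm_per_hour: float = 60.0,
    merge_gap_s: float = 30.0,
    trim_start_s: float = 10.0,
) -> list[tuple[str, SensorTrace]]:
    """Rising CO2 sub-intervals per phase, restricted to recirculation.

    Within each session phase the trace is smoothed and maximal runs with
    smoothed slope above ``-slope_tolerance_ppm_per_hour`` are kept (a small
    negative tolerance so sensor noise near steady state does not fragment a
    segment; a purge drains the cabin orders of magnitude faster and is
    always excluded).  Runs closer than ``merge_gap_s`` are merged, the first
    ``trim_start_s`` seconds are dropped as the sensor transient, and
    segments shorter than ``min_duration_s`` (or with fewer than 8 samples)
    are discarded.
    """
    out: list[tuple[str, SensorTrace]] = []
    log = actuation_log or []
    for phase in session.phases:
        sub = co2.crop(phase.start, phase.end)
        if len(sub) < 8:
            continue
        recirc = _vent_mod.recirculation_intervals(log, phase.start, phase.end)
        if not recirc:
            continue
        dt = float(np.median(np.diff(sub.timestamps)))
        window = max(1, int(round(smooth_window_s / dt)))
        smoothed = _moving_average(sub.values, window)
        slope = np.gradient(smoothed, sub.timestamps) * 3600.0  # ppm/hour
        rising = slope >= -slope_tolerance_ppm_per_hour
        in_recirc = np.zeros(len(sub), dtype=bool)
        for a, b in recirc:
            in_recirc |= (sub.timestamps >= a) & (sub.timestamps <= b)
        mask = rising & in_recirc
        # merge short gaps
        gap = max(1, int(round(merge_gap_s / dt)))
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        runs: list[list[int]] = [[idx[0], idx[0]]]
        for i in idx[1:]:
            if i - runs[-1][1] <= gap and np.all(
                in_recirc[runs[-1][1] : i + 1]
            ):
                runs[-1][1] = i
            else:
                runs.append([i, i])
        for a, b in runs:
            t0 = sub.timestamps[a] + trim_start_s
            t1 = sub.timestamps[b]
            if t1 - t0 < min_duration_s:
                continue
            seg = sub.crop(t0, t1)
            if len(seg) >= 8:
                out.append((phase.label, seg))
    return out


def fit_kgen(
    segment: SensorTrace,
    lambda_acc: float,
    co2_outdoor: float = 450.0,
) -> Co2FitResult:
    """Nonlinear least-squares fit of (k_gen, Ci) on one accumulation segment.

    The air-exchange rate and the outdoor concentration are held fixed.
    Initialization uses the first sample for Ci and the identity
    ``k_gen = initial slope + lambda * (Ci - C0)``, which is exact at t=0.
    """
    if len(segment) < 8:
        raise ValueError(f"segment too short to fit ({len(segment)} samples, need >= 8)")
    if not lambda_acc > 0:
        raise ValueError("lambda_acc must be > 0")
    t = segment.timestamps - segment.timestamps[0]
    y = segment.values
    c_i0 = float(y[0])
    n0 = max(3, min(len(y), int(0.1 * len(y))))
    slope0 = float(np.polyfit(t[:n0], y[:n0], 1)[0]) * 3600.0  # ppm/hour
    k0 = max(0.0, slope0 + lambda_acc * (c_i0 - co2_outdoor))

    def residuals(p):
        k_gen, c_i = p
        return co2_closed_form(t, co2_outdoor, c_i, k_gen, lambda_acc) - y

    sol = least_squares(
        residuals,
        x0=[k0, max(c_i0, 0.0)],
        bounds=([-np.inf, 0.0], [np.inf, np.inf]),
        method="trf",
    )
    if not sol.success:
        raise RuntimeError(f"k_gen fit did not converge: {sol.message}")
    k_fit, c_i_fit = sol.x
    clipped = False
    if k_fit < 0:
        warnings.warn("fitted k_gen < 0; clipping to 0", stacklevel=2)
        k_fit, clipped = 0.0, True
    rmse = float(np.sqrt(np.mean(residuals([k_fit, c_i_fit]) ** 2)))
    params = Co2ModelParams(co2_outdoor, float(c_i_fit), float(k_fit), float(lambda_acc))
    return Co2FitResult(params, rmse, len(segment), clipped)


# ---------------------------------------------------------------------------
# energy expenditure
# ---------------------------------------------------------------------------


def weir_ee(vco2_ml_min: float, constants: MetabolicConstants | None = None) -> float:
    """Fixed-RQ Weir combination: EE from VCO2 (mL/min)."""
    c = constants or MetabolicConstants()
    return c.weir_slope * vco2_ml_min


def vco2_from_ee(ee: float, constants: MetabolicConstants | None = None) -> float:
    c = constants or MetabolicConstants()
    return ee / c.weir_slope


def ee_from_kgen(
    params: Co2ModelParams,
    session: SessionDescriptor,
    stpd: StpdInputs | float,
    constants: MetabolicConstants | None = None,
    phase: str = "",
    fit_rmse: float = float("nan"),
    segment: tuple[float, float] = (float("nan"), float("nan")),
) -> MetabolicEstimate:
    """Convert a fitted generation rate into a per-phase metabolic estimate.

    ``stpd`` may be a precomputed CF_STPD value or the raw cabin conditions.
    """
    c = constants or MetabolicConstants()
    cf_stpd = stpd if isinstance(stpd, (int, float)) else stpd_factor(stpd, c)
    k_prime = c.kgen_prime(params.k_gen)
    vco2 = k_prime * 1e-6 * session.cabin_volume_ml * cf_stpd / 60.0
    ee = weir_ee(vco2, c)
    return MetabolicEstimate(
        phase=phase,
        k_gen=params.k_gen,
        k_gen_prime=k_prime,
        vco2=vco2,
        vo2=vco2 / c.rq,
        ee=ee,
        fit_rmse=fit_rmse,
        segment=segment,
    )


def kgen_from_ee(
    ee: float,
    cabin_volume_ml: float,
    stpd: StpdInputs | float,
    constants: MetabolicConstants | None = None,
) -> float:
    """Inverse of the EE chain: generation rate (ppm/hour) for a target EE."""
    c = constants or MetabolicConstants()
    cf_stpd = stpd if isinstance(stpd, (int, float)) else stpd_factor(stpd, c)
    vco2 = vco2_from_ee(ee, c)
    k_prime = vco2 * 60.0 / (1e-6 * cabin_volume_ml * cf_stpd)
    return c.kgen_from_prime(k_prime)


def phase_ee_change(estimates: dict[str, MetabolicEstimate]) -> HybridIndicators:
    """Percent EE changes across phases (normal->aggressive is the headline)."""
    ind = HybridIndicators()

    def pct(a: str, b: str) -> float | None:
        if a not in estimates or b not in estimates:
            return None
        ee_a = estimates[a].ee
        if ee_a <= 0:
            raise ValueError(f"EE for phase {a!r} must be positive to compute a change")
        return 100.0 * (estimates[b].ee - ee_a) / ee_a

    ind.ee_change_pct = pct("normal", "aggressive")
    ind.ee_change_parked_to_normal_pct = pct("parked", "normal")
    ind.ee_change_parked_to_aggressive_pct = pct("parked", "aggressive")
    return ind


def hybrid_indicators(
    ee_change_pct: float,
    aggressive_speed_mph: float,
    path_deviation: float = 0.0,
    reading: str = "fraction",
) -> HybridIndicators:
    """Engineered indicators combining EE change, speed and path deviation.

    ``speed_x_ee`` is aggressive speed (mph) times the percent EE change; its
    decision threshold is :data:`SPEED_EE_THRESHOLD`.  The composite feature
    under the default ``"fraction"`` reading is

        speed^2 * ee_change / (0.1 * speed) + path_deviation
        = 10 * speed * ee_change + path_deviation,

    a scaled extension of the speed x EE indicator; ``"product"`` instead
    multiplies all terms (speed^2 * ee_change * 0.1 * speed).
    """
    if aggressive_speed_mph <= 0:
        raise ValueError("aggressive speed must be > 0 for the hybrid indicators")
    speed_x_ee = aggressive_speed_mph * ee_change_pct
    if reading == "fraction":
        eq = 10.0 * aggressive_speed_mph * ee_change_pct + path_deviation
    elif reading == "product":
        eq = 0.1 * aggressive_speed_mph**3 * ee_change_pct + path_deviation
    else:
        raise ValueError(f"unknown reading {reading!r}")
    return HybridIndicators(
        ee_change_pct=ee_change_pct,
        speed_x_ee=speed_x_ee,
        eq_feature=eq,
        path_deviation=path_deviation,
    )
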