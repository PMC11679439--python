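"""Sensor-trace containers and plain-text I/O.

All timestamps are seconds since session start (floats), never wall clock:
every downstream computation (segment fitting, turn windows, interpolation)
works on elapsed time.  GPS positions are local planar XY in meters; tracks
recorded as latitude/longitude are projected with a local equirectangular
projection about the track centroid (the test circuit is ~100 m in extent,
so projection distortion is negligible).

CSV dialects are deliberately rigid so that write -> read round-trips are
bit-exact: scalar channels are ``t,value``, GPS tracks are ``t,x,y,speed``,
and metadata (channel name, units, nominal rate) travels in ``#`` comment
lines above the header.
"""

from __future__ import annotations

import json
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from shapely.geometry import LineString, Polygon, mapping, shape

__all__ = [
    "UNIT_VOCABULARY",
    "TraceValidationError",
    "TraceParseError",
    "SensorTrace",
    "GpsTrack",
    "Phase",
    "SessionDescriptor",
    "DesignatedPath",
    "mph_to_mps",
    "mps_to_mph",
    "fahrenheit_to_celsius",
    "celsius_to_fahrenheit",
    "latlon_to_local_xy",
    "read_trace_csv",
    "write_trace_csv",
    "read_gps_csv",
    "write_gps_csv",
    "read_session",
    "write_session",
    "read_path",
    "write_path_geojson",
    "read_gpx",
]

#: Closed unit vocabulary; conversions only through the explicit helpers below.
UNIT_VOCABULARY = frozenset(
    {
        "rad/s",
        "rad/s^2",
        "ppm",
        "degC",
        "%",
        "mmHg",
        "mph",
        "m",
        "m/s",
        "s",
        "kcal/day",
        "mL/min",
        "1/hour",
        "ppm/hour",
        "dimensionless",
    }
)

MPS_PER_MPH = 0.44704  # exact by definition of the international mile


class TraceValidationError(ValueError):
    """An in-memory trace or descriptor violates its invariants."""


class TraceParseError(ValueError):
    """A file could not be parsed; carries a line number where possible."""


def mph_to_mps(v):
    return np.asarray(v, dtype=float) * MPS_PER_MPH


def mps_to_mph(v):
    return np.asarray(v, dtype=float) / MPS_PER_MPH


def fahrenheit_to_celsius(f):
    return (np.asarray(f, dtype=float) - 32.0) * 5.0 / 9.0


def celsius_to_fahrenheit(c):
    return np.asarray(c, dtype=float) * 9.0 / 5.0 + 32.0


def _check_strictly_increasing(t: np.ndarray, what: str) -> None:
    if t.size > 1 and not np.all(np.diff(t) > 0):
        bad = int(np.flatnonzero(np.diff(t) <= 0)[0])
        raise TraceValidationError(
            f"{what}: timestamps must be strictly increasing "
            f"(violation at index {bad + 1}, t={t[bad + 1]!r})"
        )


@dataclass
class SensorTrace:
    """One scalar channel sampled on a strictly increasing time grid.

    Parameters
    ----------
    channel_name:
        Free-text channel identifier, e.g. ``"gyro_z"`` or ``"co2"``.
    timestamps:
        Seconds since session start, strictly increasing.
    values:
        One sample per timestamp.
    units:
        Unit string drawn from :data:`UNIT_VOCABULARY`.
    nominal_rate:
        Nominal sampling rate in Hz (10 for the gyroscope, 1 for GPS-derived
        speed, anything >= 0.05 for the cabin-environment channels).
    """

    channel_name: str
    timestamps: np.ndarray
    values: np.ndarray
    units: str
    nominal_rate: float

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.timestamps.ndim != 1 or self.values.ndim != 1:
            raise TraceValidationError("timestamps and values must be 1-D")
        if self.timestamps.size != self.values.size:
            raise TraceValidationError(
                f"length mismatch: {self.timestamps.size} timestamps vs "
                f"{self.values.size} values"
            )
        _check_strictly_increasing(self.timestamps, self.channel_name)
        if self.units not in UNIT_VOCABULARY:
            raise TraceValidationError(
                f"unknown units {self.units!r}; expected one of {sorted(UNIT_VOCABULARY)}"
            )
        if not self.nominal_rate > 0:
            raise TraceValidationError("nominal_rate must be > 0")

    def __len__(self) -> int:
        return int(self.timestamps.size)

    @property
    def duration(self) -> float:
        if len(self) == 0:
            return 0.0
        return float(self.timestamps[-1] - self.timestamps[0])

    def value_at(self, t) -> np.ndarray:
        """Linear interpolation of the channel at time(s) ``t``."""
        return np.interp(np.asarray(t, dtype=float), self.timestamps, self.values)

    def crop(self, t0: float, t1: float) -> "SensorTrace":
        """Samples with ``t0 <= t <= t1`` (inclusive)."""
        m = (self.timestamps >= t0) & (self.timestamps <= t1)
        return SensorTrace(
            self.channel_name, self.timestamps[m], self.values[m], self.units, self.nominal_rate
        )

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        if len(self) < 3:
            return True
        dt = np.diff(self.timestamps)
        return bool(np.allclose(dt, dt[0], rtol=rtol, atol=1e-9))


@dataclass
class GpsTrack:
    """GPS fixes: local planar position (m), ground speed (mph), fix error (m)."""

    timestamps: np.ndarray
    xy: np.ndarray
    speed_mph: np.ndarray
    fix_error: float = 1.0

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        self.speed_mph = np.asarray(self.speed_mph, dtype=float)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise TraceValidationError("xy must have shape (n, 2)")
        if not (self.timestamps.size == self.xy.shape[0] == self.speed_mph.size):
            raise TraceValidationError("GPS arrays must have equal length")
        _check_strictly_increasing(self.timestamps, "gps")
        if not self.fix_error > 0:
            raise TraceValidationError("fix_error must be > 0")
        if self.speed_mph.size and np.min(self.speed_mph) < 0:
            raise TraceValidationError("speed must be >= 0")

    def __len__(self) -> int:
        return int(self.timestamps.size)

    def position_at(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        x = np.interp(t, self.timestamps, self.xy[:, 0])
        y = np.interp(t, self.timestamps, self.xy[:, 1])
        return np.stack([x, y], axis=-1)

    def speed_at(self, t) -> np.ndarray:
        return np.interp(np.asarray(t, dtype=float), self.timestamps, self.speed_mph)

    def covers(self, t: float) -> bool:
        return bool(self.timestamps.size) and self.timestamps[0] <= t <= self.timestamps[-1]

    def crop(self, t0: float, t1: float) -> "GpsTrack":
        m = (self.timestamps >= t0) & (self.timestamps <= t1)
        return GpsTrack(self.timestamps[m], self.xy[m], self.speed_mph[m], self.fix_error)


PHASE_ORDER = ("parked", "normal", "aggressive")


@dataclass
class Phase:
    label: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.label not in PHASE_ORDER:
            raise TraceValidationError(f"unknown phase label {self.label!r}")
        if not self.end > self.start:
            raise TraceValidationError(f"phase {self.label!r}: end must exceed start")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class SessionDescriptor:
    """Static description of one standardized driving session.

    Phases must appear in the protocol order parked -> normal -> aggressive
    (each at most once, later ones optional) and must not overlap.
    """

    subject_id: str
    phases: list[Phase]
    cabin_volume_ml: float
    vent_co2_min_ppm: float = 600.0
    vent_co2_max_ppm: float = 900.0
    lap_count: int = 10
    lap_length_m: float = 540.0

    def __post_init__(self) -> None:
        if not self.cabin_volume_ml > 0:
            raise TraceValidationError("cabin_volume_ml must be > 0")
        if not self.vent_co2_min_ppm < self.vent_co2_max_ppm:
            raise TraceValidationError("vent thresholds: min must be < max")
        labels = [p.label for p in self.phases]
        if len(set(labels)) != len(labels):
            raise TraceValidationError("duplicate phase labels")
        order = [PHASE_ORDER.index(lb) for lb in labels]
        if order != sorted(order):
            raise TraceValidationError(
                "phases must follow the order parked -> normal -> aggressive"
            )
        for a, b in zip(self.phases, self.phases[1:]):
            if b.start < a.end:
                raise TraceValidationError(
                    f"phases {a.label!r} and {b.label!r} overlap"
                )

    def phase(self, label: str) -> Phase:
        for p in self.phases:
            if p.label == label:
                return p
        raise KeyError(label)

    def has_phase(self, label: str) -> bool:
        return any(p.label == label for p in self.phases)


@dataclass
class DesignatedPath:
    """The route the driver is asked to follow.

    ``vertices`` is the route polyline in local XY meters; ``perimeter`` is
    the parking-lot boundary polygon; ``uturn_zones`` are the regions where a
    180-degree turn is planned (one per lap of the standardized circuit).
    """

    vertices: np.ndarray
    perimeter: Polygon
    uturn_zones: list[Polygon] = field(default_factory=list)
    #: planned U-turn locations as (start, end) arc-length intervals along the
    #: route polyline; used for route-coordinate matching where parts of the
    #: chained circuit pass close to each other in XY
    uturn_route_spans: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2 or self.vertices.shape[0] < 2:
            raise TraceValidationError("path needs at least 2 XY vertices")

    @property
    def linestring(self) -> LineString:
        return LineString(self.vertices)

    def length(self) -> float:
        return float(self.linestring.length)


# ---------------------------------------------------------------------------
# projections
# ---------------------------------------------------------------------------

_EARTH_RADIUS_M = 6371000.0


def latlon_to_local_xy(lat, lon, origin: tuple[float, float] | None = None) -> np.ndarray:
    """Equirectangular projection of lat/lon (degrees) about ``origin``.

    With no origin given the centroid of the points is used.  Adequate for
    track-scale (~100 m) geometry.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if origin is None:
        origin = (float(np.mean(lat)), float(np.mean(lon)))
    lat0, lon0 = origin
    x = np.radians(lon - lon0) * _EARTH_RADIUS_M * math.cos(math.radians(lat0))
    y = np.radians(lat - lat0) * _EARTH_RADIUS_M
    return np.stack([x, y], axis=-1)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def _fmt(x: float) -> str:
    return format(float(x), ".17g")


def _read_comment_meta(lines: list[str]) -> dict[str, str]:
    meta: dict[str, str] = {}
    for ln in lines:
        body = ln.lstrip("#").strip()
        if ":" in body:
            k, v = body.split(":", 1)
            meta[k.strip()] = v.strip()
    return meta


def _split_file(file: str | Path) -> tuple[dict[str, str], str | None, list[tuple[int, str]]]:
    comments: list[str] = []
    header: str | None = None
    rows: list[tuple[int, str]] = []
    with open(file, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            ln = raw.strip()
            if not ln:
                continue
            if ln.startswith("#"):
                comments.append(ln)
            elif header is None:
                header = ln
            else:
                rows.append((lineno, ln))
    return _read_comment_meta(comments), header, rows


def write_trace_csv(trace: SensorTrace, file: str | Path) -> None:
    """Write a scalar trace; round-trips bit-exactly through repr-precision."""
    with open(file, "w", encoding="utf-8") as fh:
        fh.write(f"# channel: {trace.channel_name}\n")
        fh.write(f"# units: {trace.units}\n")
        fh.write(f"# rate_hz: {_fmt(trace.nominal_rate)}\n")
        fh.write("t,value\n")
        for t, v in zip(trace.timestamps, trace.values):
            fh.write(f"{_fmt(t)},{_fmt(v)}\n")


def read_trace_csv(file: str | Path) -> SensorTrace:
    meta, header, rows = _split_file(file)
    if header != "t,value":
        raise TraceParseError(f"{file}: expected header 't,value', got {header!r}")
    ts, vs = [], []
    for lineno, ln in rows:
        parts = ln.split(",")
        if len(parts) != 2:
            raise TraceParseError(f"{file}:{lineno}: expected 2 fields, got {len(parts)}")
        try:
            ts.append(float(parts[0]))
            vs.append(float(parts[1]))
        except ValueError as exc:
            raise TraceParseError(f"{file}:{lineno}: {exc}") from exc
    return SensorTrace(
        channel_name=meta.get("channel", Path(file).stem),
        timestamps=np.array(ts, dtype=float),
        values=np.array(vs, dtype=float),
        units=meta.get("units", "dimensionless"),
        nominal_rate=float(meta.get("rate_hz", 1.0)),
    )


def write_gps_csv(track: GpsTrack, file: str | Path) -> None:
    with open(file, "w", encoding="utf-8") as fh:
        fh.write("# channel: gps\n")
        fh.write("# units: m,mph\n")
        fh.write(f"# fix_error_m: {_fmt(track.fix_error)}\n")
        fh.write("t,x,y,speed\n")
        for t, (x, y), s in zip(track.timestamps, track.xy, track.speed_mph):
            fh.write(f"{_fmt(t)},{_fmt(x)},{_fmt(y)},{_fmt(s)}\n")


def read_gps_csv(file: str | Path) -> GpsTrack:
    meta, header, rows = _split_file(file)
    if header != "t,x,y,speed":
        raise TraceParseError(f"{file}: expected header 't,x,y,speed', got {header!r}")
    data = []
    for lineno, ln in rows:
        parts = ln.split(",")
        if len(parts) != 4:
            raise TraceParseError(f"{file}:{lineno}: expected 4 fields, got {len(parts)}")
        try:
            data.append([float(p) for p in parts])
        except ValueError as exc:
            raise TraceParseError(f"{file}:{lineno}: {exc}") from exc
    arr = np.array(data, dtype=float).reshape(-1, 4)
    return GpsTrack(
        timestamps=arr[:, 0],
        xy=arr[:, 1:3],
        speed_mph=arr[:, 3],
        fix_error=float(meta.get("fix_error_m", 1.0)),
    )


# ---------------------------------------------------------------------------
# session descriptor JSON
# ---------------------------------------------------------------------------


def read_session(file: str | Path) -> SessionDescriptor:
    with open(file, "r", encoding="utf-8") as fh:
        obj = json.load(fh)
    for key in ("subject_id", "phases", "cabin_volume_ml"):
        if key not in obj:
            raise TraceValidationError(f"session descriptor missing required field {key!r}")
    phases = [Phase(p["label"], float(p["start_s"]), float(p["end_s"])) for p in obj["phases"]]
    thr = obj.get("vent_thresholds", {})
    return SessionDescriptor(
        subject_id=str(obj["subject_id"]),
        phases=phases,
        cabin_volume_ml=float(obj["cabin_volume_ml"]),
        vent_co2_min_ppm=float(thr.get("min_ppm", 600.0)),
        vent_co2_max_ppm=float(thr.get("max_ppm", 900.0)),
        lap_count=int(obj.get("lap_count", 10)),
        lap_length_m=float(obj.get("lap_length_m", 540.0)),
    )


def write_session(session: SessionDescriptor, file: str | Path) -> None:
    obj = {
        "subject_id": session.subject_id,
        "phases": [
            {"label": p.label, "start_s": p.start, "end_s": p.end} for p in session.phases
        ],
        "cabin_volume_ml": session.cabin_volume_ml,
        "vent_thresholds": {
            "min_ppm": session.vent_co2_min_ppm,
            "max_ppm": session.vent_co2_max_ppm,
        },
        "lap_count": session.lap_count,
        "lap_length_m": session.lap_length_m,
    }
    with open(file, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# designated path (GeoJSON or XY CSV)
# ---------------------------------------------------------------------------


def write_path_geojson(path: DesignatedPath, file: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"role": "path"},
            "geometry": mapping(LineString(path.vertices)),
        },
        {
            "type": "Feature",
            "properties": {"role": "perimeter"},
            "geometry": mapping(path.perimeter),
        },
    ]
    for i, zone in enumerate(path.uturn_zones):
        props = {"role": "uturn_zone", "lap": i}
        if i < len(path.uturn_route_spans):
            props["s_start"], props["s_end"] = path.uturn_route_spans[i]
        features.append(
            {"type": "Feature", "properties": props, "geometry": mapping(zone)}
        )
    with open(file, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
        fh.write("\n")


def read_path(file: str | Path) -> DesignatedPath:
    """Read a designated path from GeoJSON, or from a bare ``x,y`` CSV.

    A CSV path gets a perimeter constructed as a 15 m buffer of the polyline
    and no planned U-turn zones.
    """
    file = Path(file)
    if file.suffix.lower() in {".geojson", ".json"}:
        with open(file, "r", encoding="utf-8") as fh:
            obj = json.load(fh)
        verts = None
        perimeter = None
        zones: list[tuple[int, Polygon, tuple[float, float] | None]] = []
        for feat in obj.get("features", []):
            props = feat.get("properties", {})
            role = props.get("role")
            geom = shape(feat["geometry"])
            if role == "path":
                verts = np.asarray(geom.coords, dtype=float)
            elif role == "perimeter":
                perimeter = geom
            elif role == "uturn_zone":
                span = None
                if "s_start" in props and "s_end" in props:
                    span = (float(props["s_start"]), float(props["s_end"]))
                zones.append((int(props.get("lap", len(zones))), geom, span))
        if verts is None:
            raise TraceParseError(f"{file}: no feature with role 'path'")
        if perimeter is None:
            perimeter = LineString(verts).buffer(15.0)
        zones.sort(key=lambda z: z[0])
        spans = [sp for _, _, sp in zones if sp is not None]
        return DesignatedPath(
            verts,
            perimeter,
            [z for _, z, _ in zones],
            spans if len(spans) == len(zones) else [],
        )
    # XY CSV
    verts = []
    with open(file, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            ln = raw.strip()
            if not ln or ln.startswith("#") or ln.lower().startswith("x"):
                continue
            parts = ln.split(",")
            if len(parts) != 2:
                raise TraceParseError(f"{file}:{lineno}: expected 'x,y'")
            verts.append([float(parts[0]), float(parts[1])])
    arr = np.asarray(verts, dtype=float)
    return DesignatedPath(arr, LineString(arr).buffer(15.0), [])


def read_gpx(file: str | Path, fix_error: float = 1.0) -> GpsTrack:
    """Import a GPX track (``trk/trkseg/trkpt`` with lat, lon, time, speed).

    Times are converted to seconds since the first point; positions are
    projected to local XY about the track centroid.  Speed is read from a
    ``speed`` extension element (m/s, converted to mph) when present, else
    derived from successive positions.
    """
    ns = {"gpx": "http://www.topografix.com/GPX/1/1"}
    tree = ET.parse(file)
    lats, lons, times, speeds = [], [], [], []
    for pt in tree.getroot().iter("{http://www.topografix.com/GPX/1/1}trkpt"):
        lats.append(float(pt.attrib["lat"]))
        lons.append(float(pt.attrib["lon"]))
        t_el = pt.find("gpx:time", ns)
        if t_el is None or t_el.text is None:
            raise TraceParseError(f"{file}: trkpt without time")
        from datetime import datetime

        times.append(datetime.fromisoformat(t_el.text.replace("Z", "+00:00")).timestamp())
        sp = None
        for el in pt.iter():
            if el.tag.endswith("speed"):
                sp = float(el.text)  # m/s
        speeds.append(sp)
    if not lats:
        raise TraceParseError(f"{file}: no track points")
    t = np.array(times) - times[0]
    xy = latlon_to_local_xy(lats, lons)
    if any(s is None for s in speeds):
        d = np.linalg.norm(np.diff(xy, axis=0), axis=1)
        dt = np.diff(t)
        v = np.concatenate([[0.0], d / np.where(dt > 0, dt, np.inf)])
        speed_mph = np.asarray(mps_to_mph(v))
    else:
        speed_mph = np.asarray(mps_to_mph(np.array(speeds, dtype=float)))
    return GpsTrack(t, xy, speed_mph, fix_error=fix_error)
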