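"""Path-discrepancy scoring: route adherence as a high-level cognitive marker.

Five criteria are assessed against the designated path:

* ``uturns_missed`` — a planned U-turn zone was traversed without a
  180-degree turn being performed in it;
* ``uturns_unplanned`` — a 180-degree turn performed outside every planned
  zone (and not part of a consecutive pair);
* ``uturns_consecutive`` — two successive 180-degree turns with no
  90-degree turn between them (counted as pairs);
* ``off_path`` — a maximal run of fixes at least eight GPS-error radii
  (8 m at the +/- 1 m fix error) from the path but inside the lot perimeter;
* ``exited_path`` — a run containing at least one fix outside the perimeter
  (such a run is not double-counted as off-path).

Each criterion's occurrence count maps to points through a configurable
score table; the total is the PathDeviation score fed to the composite
indicator and the classifier.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import Point

from .traces import DesignatedPath, GpsTrack
from .turns import TurnEvent

__all__ = [
    "CRITERIA",
    "ScoreTable",
    "PathEvent",
    "PathDiscrepancyReport",
    "detect_uturn_events",
    "detect_off_path",
    "score_path",
    "path_discrepancy_report",
]

CRITERIA = (
    "uturns_missed",
    "uturns_unplanned",
    "uturns_consecutive",
    "off_path",
    "exited_path",
)

_DEFAULT_WEIGHTS = {
    "uturns_missed": 3.0,
    "uturns_unplanned": 2.0,
    "uturns_consecutive": 2.0,
    "off_path": 1.0,
    "exited_path": 4.0,
}


@dataclass
class ScoreTable:
    """Occurrence -> points mapping per criterion.

    The default maps each occurrence to a fixed weight (monotone and
    linear); ``caps`` optionally bounds the per-criterion points.  Load a
    custom table from JSON with :meth:`from_json` to swap in an official
    scoring guide verbatim.
    """

    weights: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_WEIGHTS))
    caps: dict[str, float] = field(default_factory=dict)
    version: str = "default-linear-v1"

    def __post_init__(self) -> None:
        unknown = set(self.weights) - set(CRITERIA)
        if unknown:
            raise ValueError(f"unknown criteria in score table: {sorted(unknown)}")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("score weights must be >= 0")

    def points(self, criterion: str, count: int) -> float:
        if criterion not in self.weights:
            raise ValueError(f"criterion {criterion!r} missing from score table")
        pts = self.weights[criterion] * count
        if criterion in self.caps:
            pts = min(pts, self.caps[criterion])
        return pts

    @classmethod
    def from_json(cls, file: str | Path) -> "ScoreTable":
        with open(file, "r", encoding="utf-8") as fh:
            obj = json.load(fh)
        return cls(
            weights={k: float(v) for k, v in obj.get("weights", {}).items()},
            caps={k: float(v) for k, v in obj.get("caps", {}).items()},
            version=obj.get("version", "custom"),
        )


@dataclass
class PathEvent:
    criterion: str
    time_s: float
    location: tuple[float, float]
    lap_index: int = -1
    max_deviation_m: float = float("nan")


@dataclass
class PathDiscrepancyReport:
    counts: dict[str, int]
    scores: dict[str, float]
    total_score: float
    events: list[PathEvent]
    unlocatable_uturns: int = 0
    table_version: str = "default-linear-v1"


# ---------------------------------------------------------------------------
# route matching and U-turn criteria
# ---------------------------------------------------------------------------


def match_route_position(
    track: GpsTrack,
    path: DesignatedPath,
    backtrack_m: float = 10.0,
    slack_m: float = 10.0,
) -> np.ndarray:
    """Monotone projection of the track onto the route polyline.

    Returns the arc-length coordinate (m) along the designated path for each
    fix.  The projection is constrained to a window moving forward with the
    vehicle (a little backtracking is allowed for noise), which keeps the
    match unambiguous where the chained circuit passes close to itself in
    XY.  Lateral deviations project to the nearest on-route point, so route
    progress is tracked through excursions as well.
    """
    verts = path.vertices
    seglen = np.linalg.norm(np.diff(verts, axis=0), axis=1)
    s_v = np.concatenate([[0.0], np.cumsum(seglen)])
    dt = np.diff(track.timestamps, prepend=track.timestamps[0] - 1.0)
    step = track.speed_mph * 0.44704 * dt  # expected per-fix progress (m)
    out = np.empty(len(track))
    s_prev = 0.0
    for i in range(len(track)):
        lo = np.searchsorted(s_v, s_prev - backtrack_m)
        hi = np.searchsorted(s_v, s_prev + 1.5 * max(step[i], 1.0) + slack_m)
        hi = max(hi, lo + 2)
        cand = verts[lo:hi]
        d = np.linalg.norm(cand - track.xy[i], axis=1)
        j = lo + int(np.argmin(d))
        s_prev = float(s_v[j])
        out[i] = s_prev
    return out


def detect_uturn_events(
    turns: list[TurnEvent],
    track: GpsTrack,
    path: DesignatedPath,
    span_margin_m: float = 6.0,
    time_margin_s: float = 2.0,
) -> tuple[dict[str, int], list[PathEvent], int]:
    """Classify detected 180-degree turns against the planned U-turn plan.

    Planned-versus-unplanned classification and missed-turn detection work
    in route coordinates (arc length along the designated polyline): a
    U-turn is planned when the vehicle's route position at the peak lies in
    a planned span, and a span is missed when the track traverses it with no
    180-degree turn during the traversal.  Consecutive U-turns are pairs of
    successive 180-degree events with no 90-degree turn between them; pair
    members are not double-counted as unplanned.  Returns (counts, events,
    number of U-turns that could not be located on the track).
    """
    ordered = sorted((e for e in turns if e.kind in ("left90", "right90", "uturn180")),
                     key=lambda e: e.peak_time)
    uturns = [e for e in ordered if e.kind == "uturn180"]

    spans = list(path.uturn_route_spans)
    if not spans and path.uturn_zones:
        # fall back to projecting zone centroids onto the route
        line = path.linestring
        for zone in path.uturn_zones:
            s_c = line.project(zone.centroid)
            r = float(np.sqrt(zone.area / np.pi))
            spans.append((s_c - r, s_c + r))

    located: list[tuple[TurnEvent, Point | None]] = []
    unlocatable = 0
    for e in uturns:
        if track.covers(e.peak_time):
            located.append((e, Point(track.position_at(e.peak_time))))
        else:
            located.append((e, None))
            unlocatable += 1

    # consecutive pairs: adjacent U-turns with no 90-degree event between
    consecutive_members: set[int] = set()
    n_consecutive = 0
    idx_of = {id(e): i for i, e in enumerate(ordered)}
    for a, b in zip(uturns, uturns[1:]):
        between = ordered[idx_of[id(a)] + 1 : idx_of[id(b)]]
        if not any(e.kind in ("left90", "right90") for e in between):
            n_consecutive += 1
            consecutive_members.update((id(a), id(b)))

    events: list[PathEvent] = []
    n_unplanned = 0
    n_missed = 0
    if len(track) and spans:
        s = match_route_position(track, path)
        for e, pt in located:
            if pt is None:
                continue
            s_e = float(np.interp(e.peak_time, track.timestamps, s))
            planned = any(a - span_margin_m <= s_e <= b + span_margin_m for a, b in spans)
            if not planned and id(e) not in consecutive_members:
                n_unplanned += 1
                events.append(PathEvent("uturns_unplanned", e.peak_time, (pt.x, pt.y)))
        u_times = [e.peak_time for e, pt in located if pt is not None]
        for si, (a, b) in enumerate(spans):
            inside = np.flatnonzero((s >= a - 1.0) & (s <= b + 1.0))
            if inside.size == 0:
                continue  # span never reached (short track)
            t_a = float(track.timestamps[inside[0]]) - time_margin_s
            t_b = float(track.timestamps[inside[-1]]) + time_margin_s
            if not any(t_a <= tu <= t_b for tu in u_times):
                n_missed += 1
                j = int(inside[inside.size // 2])
                events.append(
                    PathEvent(
                        "uturns_missed",
                        float(track.timestamps[j]),
                        (float(track.xy[j, 0]), float(track.xy[j, 1])),
                        lap_index=si,
                    )
                )
    elif len(track):
        # no plan available: every located U-turn is unplanned
        for e, pt in located:
            if pt is not None and id(e) not in consecutive_members:
                n_unplanned += 1
                events.append(PathEvent("uturns_unplanned", e.peak_time, (pt.x, pt.y)))

    counts = {
        "uturns_missed": n_missed,
        "uturns_unplanned": n_unplanned,
        "uturns_consecutive": n_consecutive,
    }
    return counts, events, unlocatable


# ---------------------------------------------------------------------------
# off-path / exited-path criteria
# ---------------------------------------------------------------------------


def detect_off_path(
    track: GpsTrack,
    path: DesignatedPath,
    gps_error: float | None = None,
    *,
    deviation_multiple: float = 8.0,
    merge_gap_fixes: int = 3,
) -> tuple[dict[str, int], list[PathEvent]]:
    """Find off-path and exited-path excursions.

    A fix is deviating when its perpendicular distance to the designated
    polyline is at least ``deviation_multiple`` times the GPS error.
    Maximal runs of deviating fixes (runs separated by fewer than
    ``merge_gap_fixes`` fixes are merged) become one event each: exited-path
    when any fix in the run lies outside the lot perimeter (boundary counts
    as inside), off-path otherwise.
    """
    if path.vertices.shape[0] < 2:
        raise ValueError("degenerate designated path (< 2 vertices)")
    if gps_error is None:
        gps_error = track.fix_error
    if len(track) == 0:
        return {"off_path": 0, "exited_path": 0}, []
    line = path.linestring
    pts = shapely.points(track.xy)
    dist = shapely.distance(pts, line)
    inside = shapely.covers(path.perimeter, pts)
    deviating = dist >= deviation_multiple * gps_error

    idx = np.flatnonzero(deviating)
    counts = {"off_path": 0, "exited_path": 0}
    events: list[PathEvent] = []
    if idx.size == 0:
        return counts, events
    runs: list[list[int]] = [[idx[0], idx[0]]]
    for i in idx[1:]:
        if i - runs[-1][1] < merge_gap_fixes:
            runs[-1][1] = i
        else:
            runs.append([i, i])
    for a, b in runs:
        run = slice(a, b + 1)
        crit = "exited_path" if not np.all(inside[run]) else "off_path"
        counts[crit] += 1
        j = a + int(np.argmax(dist[run]))
        events.append(
            PathEvent(
                crit,
                float(track.timestamps[j]),
                (float(track.xy[j, 0]), float(track.xy[j, 1])),
                max_deviation_m=float(dist[j]),
            )
        )
    return counts, events


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def score_path(
    counts: dict[str, int],
    table: ScoreTable | None = None,
    events: list[PathEvent] | None = None,
    unlocatable_uturns: int = 0,
) -> PathDiscrepancyReport:
    """Map criterion counts to points and the total PathDeviation score."""
    table = table or ScoreTable()
    full = {k: int(counts.get(k, 0)) for k in CRITERIA}
    if any(v < 0 for v in full.values()):
        raise ValueError("criterion counts must be >= 0")
    scores = {k: table.points(k, v) for k, v in full.items()}
    return PathDiscrepancyReport(
        counts=full,
        scores=scores,
        total_score=float(sum(scores.values())),
        events=list(events or []),
        unlocatable_uturns=unlocatable_uturns,
        table_version=table.version,
    )


def path_discrepancy_report(
    turns: list[TurnEvent],
    track: GpsTrack,
    path: DesignatedPath,
    table: ScoreTable | None = None,
    gps_error: float | None = None,
) -> PathDiscrepancyReport:
    """Full path analysis of one driving phase: all five criteria + score."""
    u_counts, u_events, unloc = detect_uturn_events(turns, track, path)
    d_counts, d_events = detect_off_path(track, path, gps_error)
    counts = {**u_counts, **d_counts}
    return score_path(counts, table, u_events + d_events, unloc)
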