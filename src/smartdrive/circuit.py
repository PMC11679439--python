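"""Standardized-circuit geometry and the maneuver schedule.

One lap of the standardized test is 540 m of straight sections with
4 consecutive left 90-degree turns, then one 180-degree U-turn, then
3 consecutive right 90-degree turns.  Laps are chained head-to-tail: the
stated turn sequence changes heading by a net +270 degrees per lap, so a lap
cannot literally close on itself; each simulated lap therefore starts at the
end pose of the previous one, and the designated path is the full chained
polyline.  Turn handedness uses the ENU convention (left turn => positive
gyroscope z) by default; the flag ``left_positive`` flips it globally.

Corner arcs are driven with raised-cosine angular-velocity pulses: smooth,
single-peaked, and integrating exactly to the corner angle.  Segment
boundaries are snapped to the gyroscope sample grid so that the sampled
pulse integrates to the corner angle to machine precision (the trapezoid
rule is exact over a whole period of the cosine); the snap error is absorbed
into the lap length, which stays within +/- 0.5 m of 540 m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Maneuver", "CircuitGeometry", "TURN_SEQUENCE"]

#: Per-lap turn sequence of the standardized circuit.
TURN_SEQUENCE: tuple[str, ...] = (
    "left90",
    "left90",
    "left90",
    "left90",
    "uturn180",
    "right90",
    "right90",
    "right90",
)

_TURN_ANGLE = {"left90": math.pi / 2, "uturn180": math.pi, "right90": -math.pi / 2}


@dataclass
class Maneuver:
    """One schedule segment: a straight or a turn arc, on the session timeline."""

    kind: str  # 'straight' | 'left90' | 'uturn180' | 'right90'
    t_start: float
    t_end: float
    dtheta: float  # signed heading change over the segment (rad); 0 for straights
    lap_index: int
    straight_index: int = -1  # position of a straight within its lap (0..8)

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    @property
    def t_mid(self) -> float:
        return 0.5 * (self.t_start + self.t_end)


@dataclass
class CircuitGeometry:
    """Parameters of the rectangular standardized circuit."""

    lap_length_m: float = 540.0
    lap_count: int = 10
    corner_radius_m: float = 6.0
    # the U-turn arc apex must stand clear of the adjacent straights so the
    # planned-turn zone is entered only when actually turning around
    uturn_radius_m: float = 6.0
    left_positive: bool = True
    #: relative lengths of the 9 straight sections of a lap; the two long
    #: sections (indices 2 and 6) are the rectangle's long sides
    straight_weights: tuple[float, ...] = field(
        default=(0.8, 0.7, 2.2, 0.7, 0.8, 0.9, 2.2, 0.7, 1.0)
    )

    def turn_angle(self, kind: str) -> float:
        a = _TURN_ANGLE[kind]
        return a if self.left_positive else -a

    def segment_lengths(self) -> list[tuple[str, float]]:
        """(kind, arc length m) for the 17 segments of one lap."""
        arcs = {
            "left90": self.corner_radius_m * math.pi / 2,
            "right90": self.corner_radius_m * math.pi / 2,
            "uturn180": self.uturn_radius_m * math.pi,
        }
        total_arc = sum(arcs[k] for k in TURN_SEQUENCE)
        straight_total = self.lap_length_m - total_arc
        if straight_total <= 0:
            raise ValueError("corner radii too large for the lap length")
        w = np.asarray(self.straight_weights, dtype=float)
        straights = straight_total * w / w.sum()
        out: list[tuple[str, float]] = []
        si = 0
        out.append(("straight", float(straights[si])))
        for kind in TURN_SEQUENCE:
            out.append((kind, arcs[kind]))
            si += 1
            out.append(("straight", float(straights[si])))
        return out

    def schedule(
        self, speed_mps: float, laps: int | None = None, dt_snap: float = 0.1
    ) -> list[Maneuver]:
        """Maneuver schedule for ``laps`` chained laps at constant speed.

        Cumulative segment boundaries are snapped to multiples of ``dt_snap``
        (the gyroscope sampling interval) so every turn pulse starts and ends
        exactly on a sample.  Snapping never accumulates: each boundary is
        rounded independently, so the lap duration error is at most
        ``dt_snap / 2``.
        """
        if not speed_mps > 0:
            raise ValueError("cannot traverse the circuit at zero speed")
        laps = self.lap_count if laps is None else laps
        segs = self.segment_lengths()
        out: list[Maneuver] = []
        ideal = 0.0
        prev_snap = 0.0
        for lap in range(laps):
            straight_i = 0
            for kind, length in segs:
                ideal += length / speed_mps
                snap = round(ideal / dt_snap) * dt_snap
                if snap <= prev_snap:  # guard against degenerate tiny segments
                    snap = prev_snap + dt_snap
                dtheta = 0.0 if kind == "straight" else self.turn_angle(kind)
                m = Maneuver(kind, prev_snap, snap, dtheta, lap, -1)
                if kind == "straight":
                    m.straight_index = straight_i
                    straight_i += 1
                out.append(m)
                prev_snap = snap
        return out
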