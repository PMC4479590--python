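"""Per-interval movement metrics: step distances and turning angles.

The unit of analysis is the interval between two consecutive fixes. Each
interval carries the Euclidean distance covered between its two fixes and the
turning angle at its first fix — the absolute deviation, in degrees in
[0, 180], of the outgoing step direction from the incoming one. 0 deg is a
straight continuation and 180 deg a full reversal; the sign of the turn is
deliberately discarded. The first interval of a trajectory has no incoming
step and its angle is undefined, as is any angle involving a zero-length step.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .io import Fix, Trajectory

#: Relative tolerance on interval duration before an interval is excluded.
DURATION_RTOL = 0.1


@dataclass(frozen=True)
class IntervalMetrics:
    """Distance and turning angle of one between-fix interval."""

    t_start: float
    t_end: float
    distance_m: float
    angle_deg: float | None


def step_distance(p: Fix, q: Fix) -> float:
    """Euclidean distance in metres between two planar fixes."""
    return math.hypot(q.x - p.x, q.y - p.y)


def turning_angle(a: Fix, b: Fix, c: Fix) -> float | None:
    """Turning angle at ``b`` between steps a->b and b->c, degrees in [0, 180].

    Returns None when either step has zero length (direction undefined).
    """
    ux, uy = b.x - a.x, b.y - a.y
    vx, vy = c.x - b.x, c.y - b.y
    if (ux == 0.0 and uy == 0.0) or (vx == 0.0 and vy == 0.0):
        return None
    delta = math.atan2(vy, vx) - math.atan2(uy, ux)
    return abs(math.degrees(math.atan2(math.sin(delta), math.cos(delta))))


def interval_metrics(
    traj: Trajectory, duration_rtol: float = DURATION_RTOL
) -> list[IntervalMetrics]:
    """Compute one :class:`IntervalMetrics` per regular consecutive fix pair.

    The angle attached to interval i (fixes i -> i+1) is the turning angle at
    fix i, which needs fix i-1; the first interval's angle is therefore
    undefined. Intervals whose duration deviates from the trajectory's nominal
    interval by more than ``duration_rtol`` are excluded (with a warning), and
    an angle is only defined when the preceding interval is itself regular.
    """
    if len(traj) < 2:
        warnings.warn(
            f"trajectory {traj.animal_id!r} has fewer than 2 fixes; no intervals",
            stacklevel=2,
        )
        return []
    t, x, y = traj.arrays()
    dt = np.diff(t)
    dx, dy = np.diff(x), np.diff(y)
    dist = np.hypot(dx, dy)
    regular = np.abs(dt - traj.interval_s) <= duration_rtol * traj.interval_s
    n_irregular = int((~regular).sum())
    if n_irregular:
        warnings.warn(
            f"excluded {n_irregular} interval(s) of irregular duration "
            f"for animal {traj.animal_id!r}",
            stacklevel=2,
        )

    heading = np.arctan2(dy, dx)
    turn = np.full(dist.shape, np.nan)
    if dist.size >= 2:
        delta = heading[1:] - heading[:-1]
        delta = np.arctan2(np.sin(delta), np.cos(delta))
        ok = (dist[1:] > 0) & (dist[:-1] > 0) & regular[:-1]
        turn[1:] = np.where(ok, np.abs(np.degrees(delta)), np.nan)

    out: list[IntervalMetrics] = []
    for i in np.flatnonzero(regular):
        angle = None if math.isnan(turn[i]) else float(turn[i])
        out.append(IntervalMetrics(float(t[i]), float(t[i + 1]), float(dist[i]), angle))
    return out


def subsample_trajectory(traj: Trajectory, factor: int) -> Trajectory:
    """Keep every ``factor``-th fix (phase 0), multiplying the nominal interval.

    This is how lower-frequency datasets are derived from a high-frequency
    record, e.g. a 12 s series from 2 s logging with ``factor=6``.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError(f"subsampling factor must be a positive integer, got {factor}")
    factor = int(factor)
    return Trajectory(
        traj.animal_id, traj.interval_s * factor, list(traj.fixes[::factor])
    )
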