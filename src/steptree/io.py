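"""Reading and writing GPS fix tables, observation logs and interval samples.

Fix tables are delimited text with one row per GPS fix; observation logs hold
one behaviour bout per row, coded against a fixed ethogram of mutually
exclusive classes. Coordinates are normalised to planar metres: tables may
carry planar ``x,y`` directly, or ``lon,lat`` degrees which are projected with
a local equirectangular approximation around the data centroid (adequate for
the <= km extents of paddock-scale tracking).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Mutually exclusive behaviour classes of the observation ethogram.
ETHOGRAM = (
    "Walking",
    "Foraging",
    "Standing",
    "Lying",
    "Drinking",
    "Grooming",
    "Social",
    "DryForage",
)

#: Mean Earth radius in metres, used by the local planar projection.
EARTH_RADIUS_M = 6371008.8

FIX_COLUMNS = ("animal_id", "timestamp")
INTERVAL_SAMPLE_COLUMNS = (
    "animal_id",
    "t_start",
    "t_end",
    "distance_m",
    "angle_deg",
    "behaviour",
    "purity",
)


@dataclass(frozen=True)
class Fix:
    """A single GNSS position fix in planar metres at an epoch-second time."""

    animal_id: str
    t: float
    x: float
    y: float


@dataclass
class Trajectory:
    """Time-ordered fixes of one animal at a nominal fix interval."""

    animal_id: str
    interval_s: float
    fixes: list[Fix] = field(default_factory=list)

    def __post_init__(self) -> None:
        times = [f.t for f in self.fixes]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("trajectory timestamps must be strictly increasing")
        if any(f.animal_id != self.animal_id for f in self.fixes):
            raise ValueError("all fixes must share the trajectory's animal_id")

    def __len__(self) -> int:
        return len(self.fixes)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (t, x, y) as float arrays."""
        t = np.array([f.t for f in self.fixes], dtype=float)
        x = np.array([f.x for f in self.fixes], dtype=float)
        y = np.array([f.y for f in self.fixes], dtype=float)
        return t, x, y

    def to_dataframe(self) -> pd.DataFrame:
        t, x, y = self.arrays()
        return pd.DataFrame(
            {"animal_id": self.animal_id, "timestamp": t, "x": x, "y": y}
        )


@dataclass(frozen=True)
class BehaviourSegment:
    """One observed behaviour bout: [t_start, t_end) with an ethogram label."""

    animal_id: str
    t_start: float
    t_end: float
    behaviour: str

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValueError(
                f"segment end must be after start "
                f"(got {self.t_start} >= {self.t_end} for {self.animal_id})"
            )
        if self.behaviour not in ETHOGRAM:
            raise ValueError(
                f"unknown behaviour {self.behaviour!r}; "
                f"ethogram labels are {', '.join(ETHOGRAM)}"
            )

    @property
    def duration_s(self) -> float:
        return self.t_end - self.t_start


def to_planar(
    lon: float | np.ndarray,
    lat: float | np.ndarray,
    origin: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Project lon/lat degrees onto local planar metres around ``origin``.

    Uses the equirectangular approximation x = R cos(lat0) dlon,
    y = R dlat (radians), accurate to well under 0.1% for extents of a few
    kilometres away from the poles.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    lon0, lat0 = float(origin[0]), float(origin[1])
    if np.any(np.abs(lat) >= 89.0) or abs(lat0) >= 89.0:
        raise ValueError("latitudes at or beyond +/-89 degrees are unsupported")
    x = EARTH_RADIUS_M * math.cos(math.radians(lat0)) * np.radians(lon - lon0)
    y = EARTH_RADIUS_M * np.radians(lat - lat0)
    return x, y


def parse_timestamps(values: pd.Series) -> np.ndarray:
    """Parse ISO-8601 strings or numeric epoch seconds to float epoch seconds."""
    numeric = pd.to_numeric(values, errors="coerce")
    if numeric.notna().all():
        return numeric.to_numpy(dtype=float)
    parsed = pd.to_datetime(values, utc=True, format="ISO8601")
    return parsed.astype("int64").to_numpy(dtype=float) / 1e9


def _modal_step(times: np.ndarray) -> float:
    steps = np.diff(times)
    if steps.size == 0:
        return float("nan")
    uniq, counts = np.unique(steps, return_counts=True)
    return float(uniq[np.argmax(counts)])


def read_fix_table(
    path,
    dialect: Mapping[str, str] | None = None,
) -> list[Trajectory]:
    """Read a delimited fix table into one :class:`Trajectory` per animal.

    ``dialect`` maps canonical column names (``animal_id``, ``timestamp``,
    ``x``, ``y``, ``lon``, ``lat``) to the file's column names. Coordinates
    must be given either as planar ``x,y`` metres or as ``lon,lat`` degrees;
    the latter are projected around the table centroid. The nominal fix
    interval is the modal time step of each animal's series.
    """
    dialect = dict(dialect or {})
    df = pd.read_csv(path)

    def col(name: str) -> str:
        actual = dialect.get(name, name)
        if actual not in df.columns:
            raise ValueError(f"fix table is missing required column {actual!r}")
        return actual

    for name in FIX_COLUMNS:
        col(name)
    has_xy = all(dialect.get(c, c) in df.columns for c in ("x", "y"))
    has_ll = all(dialect.get(c, c) in df.columns for c in ("lon", "lat"))
    if not has_xy and not has_ll:
        raise ValueError(
            "fix table is missing coordinate columns: need 'x'/'y' or 'lon'/'lat'"
        )

    t = parse_timestamps(df[col("timestamp")])
    if has_xy:
        x = df[col("x")].to_numpy(dtype=float)
        y = df[col("y")].to_numpy(dtype=float)
    else:
        lon = df[col("lon")].to_numpy(dtype=float)
        lat = df[col("lat")].to_numpy(dtype=float)
        origin = (float(np.mean(lon)), float(np.mean(lat)))
        x, y = to_planar(lon, lat, origin)
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("fix table contains non-finite coordinates")

    animals = df[col("animal_id")].astype(str).to_numpy()
    trajectories: list[Trajectory] = []
    for animal in pd.unique(animals):
        mask = animals == animal
        rows = np.flatnonzero(mask)
        order = np.argsort(t[mask], kind="stable")
        ts, xs, ys = t[mask][order], x[mask][order], y[mask][order]
        dup = np.flatnonzero(np.diff(ts) == 0)
        if dup.size:
            row = rows[order][dup[0] + 1] + 2  # 1-based, plus header line
            raise ValueError(
                f"duplicate timestamp for animal {animal!r} at file row {row}"
            )
        fixes = [Fix(animal, float(a), float(b), float(c)) for a, b, c in zip(ts, xs, ys)]
        trajectories.append(Trajectory(animal, _modal_step(ts), fixes))
    return trajectories


def read_observation_log(path) -> list[BehaviourSegment]:
    """Read behaviour bouts, validating labels and per-animal non-overlap."""
    df = pd.read_csv(path)
    for name in ("animal_id", "t_start", "t_end", "behaviour"):
        if name not in df.columns:
            raise ValueError(f"observation log is missing required column {name!r}")
    t0 = parse_timestamps(df["t_start"])
    t1 = parse_timestamps(df["t_end"])
    segments = [
        BehaviourSegment(str(a), float(s), float(e), str(b))
        for a, s, e, b in zip(df["animal_id"], t0, t1, df["behaviour"])
    ]
    validate_segments(segments)
    return segments


def validate_segments(segments: Sequence[BehaviourSegment]) -> None:
    """Raise if any animal's segments overlap (touching endpoints are fine)."""
    by_animal: dict[str, list[BehaviourSegment]] = {}
    for seg in segments:
        by_animal.setdefault(seg.animal_id, []).append(seg)
    for animal, segs in by_animal.items():
        segs = sorted(segs, key=lambda s: s.t_start)
        for prev, nxt in zip(segs, segs[1:]):
            if nxt.t_start < prev.t_end:
                raise ValueError(
                    f"overlapping segments for animal {animal!r}: "
                    f"[{prev.t_start}, {prev.t_end}) and [{nxt.t_start}, {nxt.t_end})"
                )


def write_segments(segments: Iterable[BehaviourSegment], path) -> None:
    rows = [
        {
            "animal_id": s.animal_id,
            "t_start": s.t_start,
            "t_end": s.t_end,
            "behaviour": s.behaviour,
        }
        for s in segments
    ]
    pd.DataFrame(rows, columns=["animal_id", "t_start", "t_end", "behaviour"]).to_csv(
        path, index=False
    )


def write_interval_samples(samples: Iterable, path) -> None:
    """Write interval samples as CSV; undefined angles become empty fields."""
    rows = []
    for s in samples:
        rows.append(
            {
                "animal_id": s.animal_id,
                "t_start": s.t_start,
                "t_end": s.t_end,
                "distance_m": s.distance_m,
                "angle_deg": "" if s.angle_deg is None else s.angle_deg,
                "behaviour": s.behaviour,
                "purity": s.purity,
            }
        )
    pd.DataFrame(rows, columns=list(INTERVAL_SAMPLE_COLUMNS)).to_csv(path, index=False)


def read_interval_samples(path) -> list:
    """Read back an interval-sample CSV written by :func:`write_interval_samples`."""
    from .coupling import IntervalSample  # local import to avoid a cycle

    df = pd.read_csv(path)
    for name in INTERVAL_SAMPLE_COLUMNS:
        if name not in df.columns:
            raise ValueError(f"interval-sample table is missing column {name!r}")
    out = []
    for row in df.itertuples(index=False):
        angle = None if pd.isna(row.angle_deg) else float(row.angle_deg)
        out.append(
            IntervalSample(
                animal_id=str(row.animal_id),
                t_start=float(row.t_start),
                t_end=float(row.t_end),
                distance_m=float(row.distance_m),
                angle_deg=angle,
                behaviour=str(row.behaviour),
                purity=str(row.purity),
            )
        )
    return out
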