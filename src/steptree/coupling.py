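"""Coupling observed behaviour bouts to between-fix intervals.

A between-fix interval becomes a classifiable sample once it is labelled from
the simultaneous visual observations. Two labelling modes are supported:

* ``pure`` — the interval is labelled only if a single behaviour covers
  (essentially) its whole duration; these are the training samples.
* ``dominant`` — a fully observed interval is labelled with the behaviour
  occupying the most time in it; used to score mixed intervals, emulating a
  field situation where behaviour changes between fixes go unseen.

Intervals not fully covered by observation are never labelled, and ties for
dominance drop the interval rather than break the tie arbitrarily.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import BehaviourSegment, Trajectory
from .metrics import interval_metrics

#: The four behaviours dominant enough to analyse; the rest are too rare.
DOMINANT_BEHAVIOURS = ("Foraging", "Lying", "Standing", "Walking")

#: Stationary classes pooled as "Resting" when they prove inseparable.
RESTING_POOL = {"Lying": "Resting", "Standing": "Resting"}

#: Reserved key for time without simultaneous observation.
UNOBSERVED = "unobserved"

#: An interval counts as covered/pure when coverage reaches this fraction
#: of its duration (absorbs 1 s observation-log granularity).
COVERAGE_TOL = 0.01


@dataclass(frozen=True)
class IntervalSample:
    """One labelled between-fix interval — the unit of classification."""

    animal_id: str
    t_start: float
    t_end: float
    distance_m: float
    angle_deg: float | None
    behaviour: str
    purity: str  # "pure" or "dominant"


@dataclass
class LabelledDataset:
    """Interval samples plus the fixed, ordered class vocabulary."""

    samples: list[IntervalSample]
    classes: list[str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {s.behaviour for s in self.samples} - set(self.classes)
        if bad:
            raise ValueError(f"samples carry labels outside the class set: {bad}")

    def __len__(self) -> int:
        return len(self.samples)

    def features(self) -> np.ndarray:
        """(n, 2) array of (distance_m, angle_deg); undefined angles are NaN."""
        return np.array(
            [
                [s.distance_m, np.nan if s.angle_deg is None else s.angle_deg]
                for s in self.samples
            ],
            dtype=float,
        ).reshape(len(self.samples), 2)

    def labels(self) -> np.ndarray:
        return np.array([s.behaviour for s in self.samples], dtype=object)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "animal_id": s.animal_id,
                    "t_start": s.t_start,
                    "t_end": s.t_end,
                    "distance_m": s.distance_m,
                    "angle_deg": np.nan if s.angle_deg is None else s.angle_deg,
                    "behaviour": s.behaviour,
                    "purity": s.purity,
                }
                for s in self.samples
            ]
        )


def overlap_by_behaviour(
    t_start: float, t_end: float, segments: Sequence[BehaviourSegment]
) -> dict[str, float]:
    """Seconds of each behaviour observed within [t_start, t_end).

    Time not covered by any segment is reported under the reserved
    ``"unobserved"`` key.
    """
    duration = t_end - t_start
    out: dict[str, float] = {}
    covered = 0.0
    for seg in segments:
        lo = max(t_start, seg.t_start)
        hi = min(t_end, seg.t_end)
        if hi > lo:
            out[seg.behaviour] = out.get(seg.behaviour, 0.0) + (hi - lo)
            covered += hi - lo
    if covered < duration:
        out[UNOBSERVED] = duration - covered
    return out


def label_interval(
    overlaps: Mapping[str, float],
    duration: float,
    mode: str,
    coverage_tol: float = COVERAGE_TOL,
) -> str | None:
    """Assign a behaviour label to an interval, or None if it cannot be used.

    ``pure`` requires a single behaviour to cover >= (1 - coverage_tol) of the
    duration; ``dominant`` requires full observation coverage and a unique
    maximum-time behaviour (ties are dropped).
    """
    if mode not in ("pure", "dominant"):
        raise ValueError(f"mode must be 'pure' or 'dominant', got {mode!r}")
    observed = {k: v for k, v in overlaps.items() if k != UNOBSERVED and v > 0}
    unobserved = overlaps.get(UNOBSERVED, 0.0)
    if unobserved > coverage_tol * duration:
        return None
    if not observed:
        return None
    if mode == "pure":
        if len(observed) > 1:
            # More than one behaviour present beyond tolerance?
            top = max(observed, key=observed.get)
            if duration - observed[top] > coverage_tol * duration:
                return None
            return top
        (top,) = observed
        if observed[top] < (1 - coverage_tol) * duration:
            return None
        return top
    # dominant
    best = max(observed.values())
    winners = [k for k, v in observed.items() if v == best]
    if len(winners) != 1:
        return None
    return winners[0]


def pool_classes(
    dataset: LabelledDataset, pooling: Mapping[str, str]
) -> LabelledDataset:
    """Rewrite labels through ``pooling`` (e.g. Lying/Standing -> Resting)."""
    unknown = set(pooling) - set(dataset.classes)
    if unknown:
        raise ValueError(f"pooling references unknown labels: {sorted(unknown)}")
    if not pooling:
        return LabelledDataset(
            list(dataset.samples), list(dataset.classes), dict(dataset.metadata)
        )
    samples = [
        replace(s, behaviour=pooling.get(s.behaviour, s.behaviour))
        for s in dataset.samples
    ]
    classes = sorted({pooling.get(c, c) for c in dataset.classes})
    return LabelledDataset(samples, classes, dict(dataset.metadata))


def build_labelled_dataset(
    traj: Trajectory,
    segments: Sequence[BehaviourSegment],
    mode: str = "pure",
    class_filter: Sequence[str] = DOMINANT_BEHAVIOURS,
    pooling: Mapping[str, str] | None = None,
    coverage_tol: float = COVERAGE_TOL,
    drop_undefined_angle: bool = True,
) -> LabelledDataset:
    """Metrics + labels -> a classifier-ready dataset for one trajectory.

    Intervals with no usable label, a label outside ``class_filter``, or an
    undefined turning angle (when ``drop_undefined_angle``, as the two-feature
    trees require) are dropped; ``pooling`` is applied afterwards.
    """
    segs = sorted(
        (s for s in segments if s.animal_id == traj.animal_id),
        key=lambda s: s.t_start,
    )
    keep = set(class_filter)
    samples: list[IntervalSample] = []
    for m in interval_metrics(traj):
        overlaps = overlap_by_behaviour(m.t_start, m.t_end, segs)
        label = label_interval(overlaps, m.t_end - m.t_start, mode, coverage_tol)
        if label is None or label not in keep:
            continue
        if drop_undefined_angle and m.angle_deg is None:
            continue
        samples.append(
            IntervalSample(
                traj.animal_id,
                m.t_start,
                m.t_end,
                m.distance_m,
                m.angle_deg,
                label,
                mode,
            )
        )
    if not samples:
        warnings.warn(
            f"no labelled intervals for animal {traj.animal_id!r}", stacklevel=2
        )
    dataset = LabelledDataset(
        samples,
        sorted(keep),
        {"interval_s": traj.interval_s, "mode": mode},
    )
    if pooling:
        dataset = pool_classes(dataset, pooling)
    return dataset


def concat_datasets(datasets: Sequence[LabelledDataset]) -> LabelledDataset:
    """Pool samples of several datasets sharing one class vocabulary."""
    if not datasets:
        raise ValueError("need at least one dataset")
    classes = datasets[0].classes
    for ds in datasets[1:]:
        if ds.classes != classes:
            raise ValueError("datasets have differing class vocabularies")
    samples = [s for ds in datasets for s in ds.samples]
    return LabelledDataset(samples, list(classes), dict(datasets[0].metadata))


def time_budget(
    segments: Sequence[BehaviourSegment], class_width_s: float = 1800.0
) -> pd.DataFrame:
    """Proportion of observed time per behaviour within clock-time classes.

    Observations are binned into classes of ``class_width_s`` seconds (half or
    full hours); within each class the proportions are over observed time and
    sum to 1. Index = class start time (epoch s), columns = behaviours.
    """
    if class_width_s <= 0:
        raise ValueError("class width must be positive")
    cells: dict[float, dict[str, float]] = {}
    for seg in segments:
        t = seg.t_start
        while t < seg.t_end:
            cls = np.floor(t / class_width_s) * class_width_s
            hi = min(seg.t_end, cls + class_width_s)
            cells.setdefault(float(cls), {}).setdefault(seg.behaviour, 0.0)
            cells[float(cls)][seg.behaviour] += hi - t
            t = hi
    table = pd.DataFrame.from_dict(cells, orient="index").fillna(0.0).sort_index()
    return table.div(table.sum(axis=1), axis=0)
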