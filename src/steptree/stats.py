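"""Validation statistics: splits, confusion matrices, permutation ANOVA.

Percent-correct summaries mirror the field's confusion-matrix tables: integer
percentages (half-up rounding), one "Correct (%)" figure per observed class
and an "Overall (%)" figure for the trace. Group comparisons of distances and
angles use a permutation ANOVA — the classical one-way F statistic referenced
against its label-permutation distribution — with Bonferroni-corrected
pairwise post-hoc tests, since the heavy class imbalance and unequal
variances of movement metrics rule out the parametric F test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coupling import IntervalSample, LabelledDataset


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class ConfusionMatrix:
    """Square count matrix; rows = observed classes, columns = predicted."""

    classes: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square and match the class count")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_dataframe(self) -> pd.DataFrame:
        """Counts with a 'Correct (%)' column and an 'Overall (%)' row."""
        overall, per_class = percent_correct(self)
        df = pd.DataFrame(self.counts, index=self.classes, columns=self.classes)
        df["Correct (%)"] = [
            per_class[c] if per_class[c] is not None else np.nan for c in self.classes
        ]
        col_pct = [
            _round_half_up(100 * self.counts[:, j].sum() / self.total)
            for j in range(len(self.classes))
        ]
        df.loc["Overall (%)"] = col_pct + [overall]
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)


def confusion_matrix(
    observed: Sequence[str], predicted: Sequence[str], classes: Sequence[str]
) -> ConfusionMatrix:
    """Count matrix with counts[i, j] = #(observed=class_i and predicted=class_j)."""
    classes = list(classes)
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for o, p in zip(observed, predicted, strict=True):
        if o not in index or p not in index:
            raise ValueError(f"label outside class set: {o!r} / {p!r}")
        counts[index[o], index[p]] += 1
    return ConfusionMatrix(classes, counts)


def percent_correct(
    cm: ConfusionMatrix,
) -> tuple[int, dict[str, int | None]]:
    """(overall %, per-class %) as integers, half-up rounded.

    A class never observed (zero row) has an undefined per-class value,
    reported as None rather than 0.
    """
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    per_class: dict[str, int | None] = {}
    for i, c in enumerate(cm.classes):
        row = cm.counts[i].sum()
        per_class[c] = _round_half_up(100 * cm.counts[i, i] / row) if row else None
    overall = _round_half_up(100 * np.trace(cm.counts) / cm.total)
    return overall, per_class


def split_half(
    dataset: LabelledDataset, seed: int = 0, stratify: bool = True
) -> tuple[LabelledDataset, LabelledDataset]:
    """Disjoint, exhaustive 50/50 split into (training, validation).

    Odd counts give training the extra sample; with ``stratify`` the split is
    50/50 within every class.
    """
    n = len(dataset)
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    rng = np.random.default_rng(seed)
    labels = dataset.labels()
    train_idx: list[int] = []
    if stratify:
        for c in dataset.classes:
            idx = rng.permutation(np.flatnonzero(labels == c))
            train_idx.extend(idx[: (len(idx) + 1) // 2].tolist())
    else:
        idx = rng.permutation(n)
        train_idx = idx[: (n + 1) // 2].tolist()
    mask = np.zeros(n, dtype=bool)
    mask[train_idx] = True
    train = [s for s, m in zip(dataset.samples, mask) if m]
    valid = [s for s, m in zip(dataset.samples, mask) if not m]
    meta = dict(dataset.metadata)
    return (
        LabelledDataset(train, list(dataset.classes), {**meta, "half": "training"}),
        LabelledDataset(valid, list(dataset.classes), {**meta, "half": "validation"}),
    )


def one_way_F(groups: Sequence[Sequence[float]]) -> float:
    """Classical one-way ANOVA F statistic (between MS / within MS).

    Returns ``inf`` when the within-group variance is zero but group means
    differ; raises when all values are identical (F undefined).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    n = sum(len(a) for a in arrays)
    g = len(arrays)
    if n - g < 1 or n < g + 1:
        raise ValueError("not enough residual degrees of freedom")
    pooled = np.concatenate(arrays)
    grand = pooled.mean()
    ssb = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if ssw == 0.0:
        if ssb == 0.0:
            raise ValueError("all observations identical; F undefined")
        return float("inf")
    return float((ssb / (g - 1)) / (ssw / (n - g)))


@dataclass(frozen=True)
class PermTestResult:
    """Result of a permutation test on the one-way F statistic."""

    statistic: float
    n_perm: int
    p_value: float
    groups: tuple[str, ...]
    exact: bool = False


def _f_from_assignments(
    pooled: np.ndarray, assign: np.ndarray, sizes: Sequence[int]
) -> np.ndarray:
    """Vectorised F for rows of permuted orderings of ``pooled``.

    ``assign`` is (m, n): each row a permutation of indices; groups are the
    consecutive blocks of ``sizes`` columns.
    """
    data = pooled[assign]
    n = pooled.size
    g = len(sizes)
    sst = float(((pooled - pooled.mean()) ** 2).sum())
    ssb = np.zeros(len(assign))
    start = 0
    for size in sizes:
        s = data[:, start : start + size].sum(axis=1)
        ssb += s * s / size
        start += size
    ssb -= pooled.sum() ** 2 / n
    ssw = sst - ssb
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / (g - 1)) / (ssw / (n - g))
    f = np.where((ssw <= 1e-12 * max(sst, 1.0)) & (ssb > 0), np.inf, f)
    return f


def _enumerate_assignments(n: int, sizes: Sequence[int]) -> np.ndarray:
    """All distinct assignments of n indices into ordered groups of ``sizes``."""
    rows: list[list[int]] = []

    def rec(remaining: tuple[int, ...], chosen: list[int], depth: int) -> None:
        if depth == len(sizes) - 1:
            rows.append(chosen + list(remaining))
            return
        for combo in combinations(remaining, sizes[depth]):
            rest = tuple(i for i in remaining if i not in combo)
            rec(rest, chosen + list(combo), depth + 1)

    rec(tuple(range(n)), [], 0)
    return np.array(rows, dtype=int)


def permutation_anova(
    groups: Sequence[Sequence[float]],
    n_perm: int = 999,
    seed: int = 0,
    group_names: Sequence[str] | None = None,
) -> PermTestResult:
    """Label-permutation test on the one-way F statistic.

    Samples ``n_perm`` random label permutations and reports
    p = (#{F_perm >= F_obs} + 1) / (n_perm + 1); when the number of distinct
    group assignments is <= n_perm the null distribution is enumerated exactly
    and p is the exact exceedance fraction.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    names = tuple(group_names) if group_names else tuple(
        f"group{i}" for i in range(len(arrays))
    )
    f_obs = one_way_F(arrays)
    pooled = np.concatenate(arrays)
    sizes = [len(a) for a in arrays]
    n = pooled.size
    n_arrangements = math.factorial(n)
    for size in sizes:
        n_arrangements //= math.factorial(size)
    tol = 1e-12 * max(1.0, abs(f_obs) if math.isfinite(f_obs) else 1.0)
    if n_arrangements <= n_perm:
        assign = _enumerate_assignments(n, sizes)
        # each distinct assignment appears prod(sizes!) times among orderings;
        # using one ordering per assignment weights them equally
        f_perm = _f_from_assignments(pooled, assign, sizes)
        exceed = int(np.sum(f_perm >= f_obs - tol))
        return PermTestResult(
            f_obs, int(len(assign)), exceed / len(assign), names, exact=True
        )
    rng = np.random.default_rng(seed)
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    f_perm = _f_from_assignments(pooled, order, sizes)
    exceed = int(np.sum(f_perm >= f_obs - tol))
    return PermTestResult(f_obs, n_perm, (exceed + 1) / (n_perm + 1), names)


def pairwise_permutation_tests(
    groups: Mapping[str, Sequence[float]],
    n_perm: int = 999,
    seed: int = 0,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """All unordered pairwise permutation tests with Bonferroni adjustment.

    Adjusted p = min(1, raw p x number of pairs).
    """
    if correction != "bonferroni":
        raise ValueError("only the Bonferroni correction is supported")
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    pairs = list(combinations(names, 2))
    rows = []
    for i, (a, b) in enumerate(pairs):
        res = permutation_anova(
            [groups[a], groups[b]],
            n_perm=n_perm,
            seed=seed + i,
            group_names=(a, b),
        )
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "F": res.statistic,
                "n_perm": res.n_perm,
                "p_raw": res.p_value,
                "p_adjusted": min(1.0, res.p_value * len(pairs)),
            }
        )
    return pd.DataFrame(rows)


def fraction_above_angle(
    samples: Sequence[IntervalSample],
    classes: Sequence[str] | None = None,
    threshold: float = 90.0,
) -> float:
    """Fraction of (selected-class) samples with turning angle > threshold.

    This is the stationary-behaviour artefact summary: behaviours with no true
    displacement show positional-error-driven angles concentrated towards
    180 degrees.
    """
    wanted = None if classes is None else set(classes)
    angles = [
        s.angle_deg
        for s in samples
        if s.angle_deg is not None and (wanted is None or s.behaviour in wanted)
    ]
    if not angles:
        raise ValueError("no samples with a defined angle in the selected classes")
    return float(np.mean(np.asarray(angles) > threshold))
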