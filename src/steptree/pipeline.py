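"""End-to-end experiment orchestration.

One experiment = one habitat/fix-interval condition: obtain a study (simulate
or read files), compute interval metrics, couple behaviour labels, split in
half, grow/cross-validate/prune a tree on the training half, validate on the
held-out half, score dominant-behaviour classification of mixed intervals,
and run the permutation-ANOVA group comparisons. Every random choice is
seeded and recorded, so a config reproduces its report bundle bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cart import DecisionTree
from .coupling import (
    DOMINANT_BEHAVIOURS,
    LabelledDataset,
    build_labelled_dataset,
)
from .io import (
    BehaviourSegment,
    Trajectory,
    read_fix_table,
    read_observation_log,
    write_interval_samples,
)
from .metrics import subsample_trajectory
from .model import BehaviourTreeModel, BehaviourTreeResults
from .simulate import SimConfig, config_to_dict, simulate_study
from .stats import (
    ConfusionMatrix,
    confusion_matrix,
    pairwise_permutation_tests,
    percent_correct,
    permutation_anova,
    split_half,
)


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment."""

    sim: SimConfig | None = None
    fix_table: str | None = None
    observation_log: str | None = None
    subsample_factor: int = 1
    class_filter: Sequence[str] = DOMINANT_BEHAVIOURS
    pooling: Mapping[str, str] | None = None
    min_leaf: int = 5
    k: int = 10
    repeats: int = 10
    split_seed: int = 0
    cv_seed: int = 0
    n_perm: int = 999
    run_anova: bool = True

    def __post_init__(self) -> None:
        if self.sim is None and (self.fix_table is None or self.observation_log is None):
            raise ValueError("provide either a SimConfig or fix_table + observation_log")
        for path in (self.fix_table, self.observation_log):
            if path is not None and not Path(path).exists():
                raise ValueError(f"input file does not exist: {path}")


@dataclass
class ExperimentReport:
    """In-memory report bundle of one experiment run."""

    config: ExperimentConfig
    dataset_pure: LabelledDataset
    dataset_mixed: LabelledDataset
    training: LabelledDataset
    validation: LabelledDataset
    results: BehaviourTreeResults
    cm_training: ConfusionMatrix
    cm_validation: ConfusionMatrix
    cm_mixed: ConfusionMatrix | None
    anova: pd.DataFrame | None

    @property
    def validation_overall_pct(self) -> int:
        return percent_correct(self.cm_validation)[0]

    @property
    def validation_per_class_pct(self) -> dict:
        return percent_correct(self.cm_validation)[1]

    def summary(self) -> str:
        lines = [self.results.summary()]
        overall_t, _ = percent_correct(self.cm_training)
        overall_v, per_v = percent_correct(self.cm_validation)
        lines.append(f"training overall correct:   {overall_t}%")
        lines.append(f"validation overall correct: {overall_v}%")
        for c, pct in per_v.items():
            shown = "undefined" if pct is None else f"{pct}%"
            lines.append(f"  validation {c}: {shown}")
        if self.cm_mixed is not None and self.cm_mixed.total:
            overall_m, _ = percent_correct(self.cm_mixed)
            lines.append(f"mixed-interval dominant-behaviour correct: {overall_m}%")
        return "\n".join(lines) + "\n"


def _load_study(
    config: ExperimentConfig,
) -> tuple[Trajectory, list[BehaviourSegment]]:
    if config.sim is not None:
        study = simulate_study(config.sim)
        return study.trajectory, study.truth_segments
    trajectories = read_fix_table(config.fix_table)
    if len(trajectories) != 1:
        raise ValueError(
            "experiment expects a single-animal fix table; "
            f"got {len(trajectories)} animals"
        )
    return trajectories[0], read_observation_log(config.observation_log)


def classify_mixed(
    tree: DecisionTree, dataset: LabelledDataset
) -> ConfusionMatrix:
    """Score a pure-trained tree against dominant-labelled intervals."""
    if list(dataset.classes) != list(tree.classes):
        raise ValueError(
            f"class mismatch: tree {tree.classes} vs dataset {dataset.classes}"
        )
    predicted = tree.predict(dataset.features())
    return confusion_matrix(dataset.labels(), predicted, tree.classes)


def run_experiment(
    config: ExperimentConfig, outdir: str | Path | None = None
) -> ExperimentReport:
    """Run the full pipeline; optionally write the report bundle to ``outdir``."""
    trajectory, segments = _load_study(config)
    if config.subsample_factor > 1:
        trajectory = subsample_trajectory(trajectory, config.subsample_factor)

    dataset_pure = build_labelled_dataset(
        trajectory,
        segments,
        mode="pure",
        class_filter=config.class_filter,
        pooling=config.pooling,
    )
    dataset_dominant = build_labelled_dataset(
        trajectory,
        segments,
        mode="dominant",
        class_filter=config.class_filter,
        pooling=config.pooling,
    )
    pure_starts = {s.t_start for s in dataset_pure.samples}
    dataset_mixed = LabelledDataset(
        [s for s in dataset_dominant.samples if s.t_start not in pure_starts],
        list(dataset_dominant.classes),
        {**dataset_dominant.metadata, "subset": "mixed"},
    )

    training, validation = split_half(
        dataset_pure, seed=config.split_seed, stratify=True
    )
    model = BehaviourTreeModel.from_dataset(training, min_leaf=config.min_leaf)
    results = model.fit(k=config.k, repeats=config.repeats, seed=config.cv_seed)
    cm_training = results.confusion(training, None)
    cm_validation = results.confusion(validation, None)
    cm_mixed = (
        classify_mixed(results.tree, dataset_mixed) if len(dataset_mixed) else None
    )

    anova = None
    if config.run_anova and len(dataset_pure):
        anova = movement_anova(
            dataset_pure, n_perm=config.n_perm, seed=config.cv_seed
        )

    report = ExperimentReport(
        config,
        dataset_pure,
        dataset_mixed,
        training,
        validation,
        results,
        cm_training,
        cm_validation,
        cm_mixed,
        anova,
    )
    if outdir is not None:
        write_report(report, outdir)
    return report


def movement_anova(
    dataset: LabelledDataset, n_perm: int = 999, seed: int = 0
) -> pd.DataFrame:
    """Permutation ANOVA of distance and angle across behaviours.

    One overall test per metric plus Bonferroni-corrected pairwise post-hocs.
    Undefined angles are simply absent, so the angle test runs on fewer
    samples than the distance test.
    """
    rows = []
    for metric in ("distance_m", "angle_deg"):
        groups = {
            c: [
                getattr(s, metric)
                for s in dataset.samples
                if s.behaviour == c and getattr(s, metric) is not None
            ]
            for c in dataset.classes
        }
        groups = {c: v for c, v in groups.items() if len(v) >= 2}
        if len(groups) < 2:
            continue
        overall = permutation_anova(
            list(groups.values()),
            n_perm=n_perm,
            seed=seed,
            group_names=list(groups),
        )
        rows.append(
            {
                "metric": metric,
                "group_a": "(all)",
                "group_b": "(all)",
                "F": overall.statistic,
                "n_perm": overall.n_perm,
                "p_raw": overall.p_value,
                "p_adjusted": overall.p_value,
            }
        )
        pairwise = pairwise_permutation_tests(groups, n_perm=n_perm, seed=seed)
        for _, r in pairwise.iterrows():
            rows.append({"metric": metric, **r.to_dict()})
    return pd.DataFrame(rows)


def _run_log(config: ExperimentConfig) -> dict:
    return {
        "steptree_version": __version__,
        "sim": None if config.sim is None else config_to_dict(config.sim),
        "fix_table": config.fix_table,
        "observation_log": config.observation_log,
        "subsample_factor": config.subsample_factor,
        "class_filter": list(config.class_filter),
        "pooling": None if config.pooling is None else dict(config.pooling),
        "min_leaf": config.min_leaf,
        "k": config.k,
        "repeats": config.repeats,
        "split_seed": config.split_seed,
        "cv_seed": config.cv_seed,
        "n_perm": config.n_perm,
    }


def write_report(report: ExperimentReport, outdir: str | Path) -> None:
    """Write the CSV/JSON/text artifacts of a run into ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(
        json.dumps(_run_log(report.config), indent=2, sort_keys=True) + "\n"
    )
    write_interval_samples(report.dataset_pure.samples, out / "dataset_pure.csv")
    write_interval_samples(report.dataset_mixed.samples, out / "dataset_mixed.csv")
    report.results.risk_curve.to_csv(out / "risk_curve.csv")
    (out / "tree.json").write_text(report.results.tree.to_json() + "\n")
    (out / "rules.txt").write_text(report.results.rules())
    report.cm_training.to_csv(out / "confusion_training.csv")
    report.cm_validation.to_csv(out / "confusion_validation.csv")
    if report.cm_mixed is not None:
        report.cm_mixed.to_csv(out / "confusion_mixed.csv")
    if report.anova is not None:
        report.anova.to_csv(out / "anova.csv", index=False)
    (out / "summary.txt").write_text(report.summary())
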