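"""End-to-end experiment runner: cohort -> features -> selection -> report.

An :class:`ExperimentConfig` names one cell of the study's experiment
grid — a classification task (five-class, controls/CST+/CST-, or
controls/Cl/FTD), a feature set (all 121, the published WEKA selection
for that task, WM-only, GM-only, clinical/demographic-only, or a fresh
CFS selection), and a classifier (CART, RF, NN).  ``run_experiment``
executes the pipeline and writes a self-contained report directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cfs import best_first_search
from .classify import METHODS, cross_validate
from .cohort import CohortBundle, CohortSpec, generate_cohort, load_cohort
from .features import (FeatureTable, assemble_feature_table,
                       impute_missing_with_mean, subset_features,
                       write_feature_csv)

__all__ = ["ExperimentConfig", "TASKS", "FEATURE_SETS", "run_experiment",
           "run_grid"]

logger = logging.getLogger("alspheno")

#: task name -> class codes included
TASKS = {
    "five_class": [0, 1, 2, 3, 4],
    "ctrl_cst": [0, 1, 2],
    "ctrl_cl_ftd": [0, 3, 4],
}

#: the published selection fixture matching each task
_TASK_FIXTURE = {
    "five_class": "table2",
    "ctrl_cst": "table3",
    "ctrl_cl_ftd": "table4",
}

FEATURE_SETS = ("all", "weka_fixture", "wm", "gm", "clinical_demographic",
                "cfs")


@dataclass
class ExperimentConfig:
    task: str = "five_class"
    feature_set: str = "all"
    method: str = "rf"
    cohort: CohortSpec | str | Path = field(default_factory=CohortSpec)
    seed: int = 0
    folds: int = 5
    mode: str = "fast"

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if self.feature_set not in FEATURE_SETS:
            raise ValueError(f"unknown feature set {self.feature_set!r}")
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")

    def config_hash(self) -> str:
        payload = {
            "task": self.task, "feature_set": self.feature_set,
            "method": self.method, "seed": self.seed, "folds": self.folds,
            "mode": self.mode,
            "cohort": (str(self.cohort) if isinstance(self.cohort, (str, Path))
                       else {"group_sizes": self.cohort.group_sizes,
                             "effect_config": self.cohort.effect_config,
                             "missing_rate": self.cohort.missing_rate,
                             "seed": self.cohort.seed}),
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _obtain_cohort(cfg: ExperimentConfig) -> CohortBundle:
    if isinstance(cfg.cohort, (str, Path)):
        return load_cohort(cfg.cohort)
    return generate_cohort(cfg.cohort, mode=cfg.mode)


def prepare_table(cfg: ExperimentConfig,
                  bundle: CohortBundle | None = None
                  ) -> tuple[FeatureTable, dict | None]:
    """Assemble, filter to the task's classes, impute and slice features.

    Returns the ready-to-classify table and, when a fresh CFS selection
    was run, its result as a dict.
    """
    bundle = bundle if bundle is not None else _obtain_cohort(cfg)
    table = assemble_feature_table(bundle)
    table = table.filter_classes(TASKS[cfg.task])
    table = impute_missing_with_mean(table)
    selection = None
    if cfg.feature_set == "weka_fixture":
        table = subset_features(table, _TASK_FIXTURE[cfg.task])
    elif cfg.feature_set == "cfs":
        result = best_first_search(table)
        selection = result.to_dict()
        table = subset_features(table, "custom", custom=result.selected)
    elif cfg.feature_set != "all":
        table = subset_features(table, cfg.feature_set)
    return table, selection


def run_experiment(cfg: ExperimentConfig, out_dir: str | Path) -> Path:
    """Execute one grid cell and write its report directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        chash = cfg.config_hash()
        logger.info("config %s task=%s features=%s method=%s seed=%d",
                    chash, cfg.task, cfg.feature_set, cfg.method, cfg.seed)
        table, selection = prepare_table(cfg)
        write_feature_csv(table, out / "feature_table.csv")
        if selection is not None:
            (out / "selection.json").write_text(json.dumps(selection, indent=2))
        report = cross_validate(cfg.method, table, k=cfg.folds, seed=cfg.seed)
        (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
        pd.DataFrame(report.confusion,
                     index=[f"true_{c}" for c in report.classes],
                     columns=[f"pred_{c}" for c in report.classes]) \
            .to_csv(out / "confusion.csv")
        if report.importance:
            imp = pd.Series(report.importance, name="importance") \
                .sort_values(ascending=False)
            imp.rename_axis("feature").to_csv(out / "importance.csv")
        (out / "config.json").write_text(json.dumps({
            "task": cfg.task, "feature_set": cfg.feature_set,
            "method": cfg.method, "seed": cfg.seed, "folds": cfg.folds,
            "mode": cfg.mode, "config_hash": chash,
            "n_subjects": table.n_subjects,
            "n_features": len(table.feature_names),
            "accuracy": report.accuracy,
        }, indent=2))
        logger.info("accuracy %.2f%% over %d subjects",
                    report.accuracy, table.n_subjects)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out


def run_grid(spec: CohortSpec, out_dir: str | Path, seed: int = 0,
             methods=METHODS, tasks=tuple(TASKS),
             feature_sets=("all", "weka_fixture", "wm", "gm",
                           "clinical_demographic"),
             mode: str = "fast") -> pd.DataFrame:
    """The full experiment grid (tasks x feature sets x methods).

    The cohort is generated once and shared across cells.  Returns a
    tidy accuracy table and writes one report directory per cell.
    """
    out = Path(out_dir)
    bundle = generate_cohort(spec, mode=mode)
    rows = []
    for task in tasks:
        for fs in feature_sets:
            for method in methods:
                cfg = ExperimentConfig(task=task, feature_set=fs,
                                       method=method, cohort=spec,
                                       seed=seed, mode=mode)
                cell = out / f"{task}__{fs}__{method}"
                cell.mkdir(parents=True, exist_ok=True)
                table, selection = prepare_table(cfg, bundle=bundle)
                report = cross_validate(method, table, k=cfg.folds, seed=seed)
                (cell / "report.json").write_text(
                    json.dumps(report.to_dict(), indent=2))
                if selection is not None:
                    (cell / "selection.json").write_text(
                        json.dumps(selection, indent=2))
                rows.append({"task": task, "feature_set": fs,
                             "method": method,
                             "accuracy": report.accuracy,
                             "n_subjects": table.n_subjects,
                             "n_features": len(table.feature_names)})
    grid = pd.DataFrame(rows)
    grid.to_csv(out / "grid_accuracies.csv", index=False)
    return grid
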