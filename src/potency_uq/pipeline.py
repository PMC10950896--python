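"""Experiment orchestration: classes x models x splits x training variants.

`run_experiment` reproduces the full analysis loop: for each activity class
and each random 70/30 compound split, every roster model is (optionally
hyperparameter-optimized with 5-fold CV on training data,) fit on the —
possibly balanced or reduced — training portion and evaluated on the
untouched test portion; accuracy and UQ metrics plus bin-wise confidence
are collected into a long-form report. The same split is reused across all
models and modifications of a cell so models are compared on identical
data. Per-cell failures are recorded, never fatal; completed cells are
skipped when resuming into the same output directory.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from ._rng import child_seed
from . import models as M
from . import nets as N
from .calibration_analysis import BinScheme, ModificationScheme, binwise_coverage, modify_training_set
from .synthetic_data import SyntheticClassConfig, generate_activity_class, read_activity_class_csv
from .types import ActivityClass, PredictionSet
from .uq_metrics import uq_report

log = logging.getLogger("potency_uq")

#: model roster names understood by the pipeline
ROSTER = (
    "knn-ensemble",
    "dt-ensemble",
    "single-dt",
    "single-knn",
    "ffnn-small-10",
    "ffnn-small-20",
    "ffnn-small-50",
    "ffnn-large-10",
    "ffnn-large-20",
    "ffnn-large-50",
    "mve-small",
    "mve-large",
)

REPORT_COLUMNS = [
    "class",
    "modification",
    "model",
    "split",
    "profile",
    "n_test",
    "mse",
    "r2",
    "nll",
    "A",
    "A_abs",
    "rho",
    "n_floored",
    "error",
]


@dataclass
class ExperimentConfig:
    """Full experiment description (YAML-mappable)."""

    classes: list = field(default_factory=lambda: [SyntheticClassConfig()])
    roster: tuple[str, ...] = ("knn-ensemble", "dt-ensemble", "single-dt", "single-knn")
    n_splits: int = 10
    train_fraction: float = 0.7
    modifications: tuple[str, ...] = ("original",)
    optimize: bool = False
    n_levels: int = 99
    bin_scheme: BinScheme = field(default_factory=BinScheme.equal_width)
    seed: int = 0
    profile: str = "desk"  # {"desk", "paper"}
    output_dir: Optional[Path] = None

    def validate(self) -> None:
        if not self.roster:
            raise ValueError("model roster is empty")
        if self.n_splits < 1:
            raise ValueError("n_splits must be >= 1")
        unknown = set(self.roster) - set(ROSTER)
        if unknown:
            raise ValueError(f"unknown roster models: {sorted(unknown)}")
        if self.profile not in ("desk", "paper"):
            raise ValueError(f"unknown scale profile {self.profile!r}")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text())
        classes = []
        for entry in raw.get("classes", [{}]):
            if isinstance(entry, str):
                classes.append(Path(entry))
            else:
                classes.append(SyntheticClassConfig(**entry))
        kw = {k: v for k, v in raw.items() if k != "classes"}
        for tup in ("roster", "modifications"):
            if tup in kw:
                kw[tup] = tuple(kw[tup])
        if "output_dir" in kw and kw["output_dir"] is not None:
            kw["output_dir"] = Path(kw["output_dir"])
        return cls(classes=classes, **kw)


@dataclass
class ExperimentReport:
    """Long-form metric table plus bin-wise confidence rows."""

    rows: pd.DataFrame
    bin_rows: pd.DataFrame

    def write(self, directory: Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.rows.to_csv(directory / "results.csv", index=False)
        self.bin_rows.to_csv(directory / "bin_confidence.csv", index=False)

    @classmethod
    def read(cls, directory: Path) -> "ExperimentReport":
        directory = Path(directory)
        return cls(
            rows=pd.read_csv(directory / "results.csv"),
            bin_rows=pd.read_csv(directory / "bin_confidence.csv"),
        )


def _load_class(source, index: int) -> ActivityClass:
    if isinstance(source, ActivityClass):
        return source
    if isinstance(source, SyntheticClassConfig):
        return generate_activity_class(source, class_id=f"synthetic-{index}")
    return read_activity_class_csv(source)


def _fit_predict_model(
    name: str,
    train: ActivityClass,
    test: ActivityClass,
    seed: int,
    profile: str,
    optimize: bool,
) -> PredictionSet:
    if name in ("knn-ensemble", "dt-ensemble"):
        family = name
        if optimize:
            params = M.optimize_hyperparameters(
                family, train, grid=M.default_grid(family, light=(profile == "desk")), seed=seed
            )
        else:
            params = dict(n_estimators=100, max_samples=0.75, max_features=0.5)
            if family == "knn-ensemble":
                params["k_neighbors"] = 3
        cfg = M.EnsembleConfig(base_learner=name.split("-")[0], **params)
        return M.predict_with_uncertainty(M.fit_ensemble(cfg, train, seed), test)
    if name == "single-dt":
        return M.fit_single("dt", train, seed).predict(test)
    if name == "single-knn":
        params = (
            M.optimize_hyperparameters("single-knn", train, seed=seed)
            if optimize
            else dict(k_neighbors=3)
        )
        return M.fit_single("knn", train, seed, **params).predict(test)
    if name.startswith("ffnn-"):
        _, size, rate = name.split("-")
        cfg = N.ffnn_config(size=size, dropout_rate=int(rate) / 100.0)
        if profile == "desk":
            cfg = N.desk_profile(cfg)
        return N.mc_dropout_predict(N.fit_ffnn_dropout(cfg, train, seed), test)
    if name.startswith("mve-"):
        cfg = N.mve_config(size=name.split("-")[1])
        if profile == "desk":
            cfg = N.desk_profile(cfg)
        return N.mve_predict(N.fit_mve(cfg, train, seed), test)
    raise ValueError(f"unknown model {name!r}")


def run_experiment(cfg: ExperimentConfig) -> ExperimentReport:
    """Execute the full grid; deterministic given ``cfg.seed``."""
    cfg.validate()
    done: set[tuple] = set()
    rows: list[dict] = []
    bin_rows: list[dict] = []
    if cfg.output_dir is not None and (Path(cfg.output_dir) / "results.csv").exists():
        prior = ExperimentReport.read(cfg.output_dir)
        rows = prior.rows.to_dict("records")
        bin_rows = prior.bin_rows.to_dict("records")
        done = {(r["class"], r["modification"], r["model"], r["split"]) for r in rows}

    for ci, source in enumerate(cfg.classes):
        cls = _load_class(source, ci)
        for si in range(cfg.n_splits):
            split = M.split_data(
                cls, seed=child_seed(cfg.seed, f"split-{cls.class_id}-{si}"),
                train_fraction=cfg.train_fraction,
            )
            train_full = cls.subset_ids(split.train_ids)
            test = cls.subset_ids(split.test_ids)
            for mod_mode in cfg.modifications:
                scheme = ModificationScheme(
                    mode=mod_mode, seed=child_seed(cfg.seed, f"mod-{cls.class_id}-{si}")
                )
                train = modify_training_set(train_full, scheme)
                for model_name in cfg.roster:
                    key = (cls.class_id, mod_mode, model_name, si)
                    if key in done:
                        continue
                    started = time.perf_counter()
                    row = {
                        "class": cls.class_id,
                        "modification": mod_mode,
                        "model": model_name,
                        "split": si,
                        "profile": cfg.profile,
                        "error": "",
                    }
                    try:
                        ps = _fit_predict_model(
                            model_name,
                            train,
                            test,
                            seed=child_seed(cfg.seed, f"fit-{cls.class_id}-{si}-{model_name}"),
                            profile=cfg.profile,
                            optimize=cfg.optimize,
                        ).tagged(split=str(si))
                        rep = uq_report(ps, n_levels=cfg.n_levels)
                        row.update(rep.to_row())
                        row["model"] = model_name  # keep roster name as the key
                        row["split"] = si
                        if ps.has_variance:
                            bc = binwise_coverage(ps, cfg.bin_scheme)
                            for rec in bc.to_frame().to_dict("records"):
                                bin_rows.append(
                                    {
                                        "class": cls.class_id,
                                        "modification": mod_mode,
                                        "model": model_name,
                                        "split": si,
                                        **rec,
                                    }
                                )
                    except Exception as exc:  # per-cell failures never abort the run
                        row["error"] = f"{type(exc).__name__}: {exc}"
                        log.warning("cell %s failed: %s", key, row["error"])
                    log.info(
                        "cell %s done in %.1fs", key, time.perf_counter() - started
                    )
                    rows.append({c: row.get(c) for c in REPORT_COLUMNS})
                    done.add(key)
    report = ExperimentReport(
        rows=pd.DataFrame(rows, columns=REPORT_COLUMNS),
        bin_rows=pd.DataFrame(
            bin_rows,
            columns=[
                "class", "modification", "model", "split",
                "bin_lo", "bin_hi", "count", "fraction_within", "expected", "label",
            ],
        ),
    )
    if cfg.output_dir is not None:
        report.write(cfg.output_dir)
    return report


def summarize(report: ExperimentReport) -> pd.DataFrame:
    """Median and quartiles per (model, modification) over splits x classes."""
    rows = report.rows
    ok = rows[rows["error"].fillna("") == ""]
    if ok.empty:
        raise ValueError("report contains no successful cells")
    metrics = ["mse", "r2", "nll", "A", "A_abs", "rho"]
    out = []
    for (model, mod), grp in ok.groupby(["model", "modification"], sort=True):
        entry = {"model": model, "modification": mod, "n_cells": len(grp)}
        for m in metrics:
            vals = grp[m].dropna()
            if len(vals):
                entry[f"{m}_median"] = float(vals.median())
                entry[f"{m}_q1"] = float(vals.quantile(0.25))
                entry[f"{m}_q3"] = float(vals.quantile(0.75))
            else:
                entry[f"{m}_median"] = entry[f"{m}_q1"] = entry[f"{m}_q3"] = np.nan
        out.append(entry)
    return pd.DataFrame(out)
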