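"""End-to-end experiment orchestration.

A single :class:`RunConfig` drives the whole experiment: simulate depth
scenes for each camera position, extract feature tables, tune and train
both classifiers, and evaluate them on the 30% hold-out, producing a
per-position method comparison plus Kruskal-Wallis tests.

Every stage is deterministic given the config: the master seed fans out
to per-stage seeds by fixed offsets (cow geometry: master + 100 + cow
index; rendering: master + 1000 + 10 * position index + cow index;
subsampling: master + 5; the model seeds are the master seed itself, and
the model layer adds its own documented offsets).  Stages are idempotent
and re-runnable from their on-disk artifacts: PGM scene pairs, CSV
feature tables, JSON models and metrics.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .balance import SmoteConfig
from .classifiers import (
    KNN_K_RANGE,
    NN_HIDDEN_LAYER_RANGE,
    NN_NEURON_SET,
    NnConfig,
)
from .evaluate import MetricsReport, compare_methods, comparison_table, kruskal_wallis
from .exceptions import EmptyInputError, InvalidParameterError
from .features import FeatureTable, extract_features
from .model import BodyPartKNN, BodyPartNet
from .scene_sim import build_cow, pgm_to_scene, preset_pose, render_depth, scene_to_pgm

log = logging.getLogger("cowseg")

_POSITION_ORDER = ("U", "N", "S")


@dataclass
class RunConfig:
    """All experiment knobs in one place (YAML round-trippable)."""

    positions: tuple[str, ...] = ("U", "N", "S")
    n_cows: int = 3
    noise_sigma: float = 2.0
    sacrum_height_range: tuple[float, float] = (1.43, 1.49)
    body_length_range: tuple[float, float] = (2.2, 2.6)
    max_rows_per_scene: int = 12000
    holdout_fraction: float = 0.3
    smote_k: int = 5
    knn_ks: tuple[int, ...] = KNN_K_RANGE
    knn_folds: int = 5
    nn_layer_range: tuple[int, ...] = (0, 1, 2)
    nn_neuron_set: tuple[int, ...] = (10, 50)
    nn_learning_rate: float = 0.001
    nn_batch_size: int = 256
    nn_max_epochs: int = 100
    scale_on_full: bool = False
    full_grids: bool = False
    master_seed: int = 0

    def __post_init__(self):
        bad = [p for p in self.positions if p not in _POSITION_ORDER]
        if bad:
            raise InvalidParameterError(f"unknown camera positions {bad}")
        if self.n_cows < 1:
            raise InvalidParameterError("n_cows must be >= 1")
        if not 0 < self.holdout_fraction < 1:
            raise InvalidParameterError("holdout_fraction must be in (0, 1)")
        if self.full_grids:
            self.knn_ks = KNN_K_RANGE
            self.nn_layer_range = NN_HIDDEN_LAYER_RANGE
            self.nn_neuron_set = NN_NEURON_SET

    def nn_config(self) -> NnConfig:
        return NnConfig(
            learning_rate=self.nn_learning_rate,
            batch_size=self.nn_batch_size,
            max_epochs=self.nn_max_epochs,
            seed=self.master_seed + 4,
        )

    def smote(self) -> SmoteConfig:
        return SmoteConfig(k_neighbors=self.smote_k, seed=self.master_seed + 3)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidParameterError(f"unknown config keys {sorted(unknown)}")
        for key in (
            "positions",
            "knn_ks",
            "nn_layer_range",
            "nn_neuron_set",
            "sacrum_height_range",
            "body_length_range",
        ):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


def _cow_sizes(config: RunConfig) -> list[tuple[float, float]]:
    hs = np.linspace(*config.sacrum_height_range, config.n_cows)
    ls = np.linspace(*config.body_length_range, config.n_cows)
    return list(zip(hs.tolist(), ls.tolist()))


def scene_path(outdir: Path, position: str, cow_idx: int) -> Path:
    return Path(outdir) / f"scene_{position}_{cow_idx}.pgm"


def cmd_simulate(config: RunConfig, outdir) -> list[Path]:
    """Render one scene per (camera position, cow); write PGM pairs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for p_idx, position in enumerate(config.positions):
        pose = preset_pose(position)
        for cow_idx, (h, length) in enumerate(_cow_sizes(config)):
            t0 = time.perf_counter()
            cow = build_cow(h, length, seed=config.master_seed + 100 + cow_idx)
            scene = render_depth(
                cow,
                pose=pose,
                noise_sigma=config.noise_sigma,
                seed=config.master_seed + 1000 + 10 * p_idx + cow_idx,
            )
            path = scene_path(outdir, position, cow_idx)
            scene_to_pgm(scene, path)
            paths.append(path)
            log.info(
                "simulate %s cow %d -> %s (%.2fs)",
                position, cow_idx, path.name, time.perf_counter() - t0,
            )
    return paths


def features_path(outdir: Path, position: str) -> Path:
    return Path(outdir) / f"features_{position}.csv"


def cmd_extract(config: RunConfig, scene_dir, outdir) -> list[Path]:
    """Pool per-scene feature tables into one CSV per camera position."""
    scene_dir, outdir = Path(scene_dir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for position in config.positions:
        frames = []
        for cow_idx in range(config.n_cows):
            sp = scene_path(scene_dir, position, cow_idx)
            if not sp.exists():
                raise FileNotFoundError(
                    f"missing scene {sp}; run the simulate stage first"
                )
            table = extract_features(
                pgm_to_scene(sp),
                camera_position=position,
                max_rows=config.max_rows_per_scene,
                seed=config.master_seed + 5,
            )
            frames.append(table.df)
        pooled = FeatureTable(
            pd.concat(frames, ignore_index=True), camera_position=position
        )
        out = features_path(outdir, position)
        pooled.to_csv(out)
        log.info("extract %s: %d rows -> %s", position, len(pooled), out.name)
        paths.append(out)
    return paths


def _load_features(config: RunConfig, feature_dir, position: str) -> FeatureTable:
    fp = features_path(Path(feature_dir), position)
    if not fp.exists():
        raise FileNotFoundError(f"missing features {fp}; run the extract stage first")
    table = FeatureTable.from_csv(fp, camera_position=position)
    if len(table) == 0:
        raise EmptyInputError(f"feature table {fp} is empty")
    return table


def cmd_train_knn(config: RunConfig, feature_dir, outdir, position: str):
    """Tune and fit the kNN model for one position; persist artifacts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = _load_features(config, feature_dir, position)
    res = BodyPartKNN(
        table,
        holdout_fraction=config.holdout_fraction,
        seed=config.master_seed,
        smote=config.smote(),
        scale_on_full=config.scale_on_full,
    ).fit(ks=config.knn_ks, folds=config.knn_folds)
    res.model.to_json(outdir / f"knn_{position}.json")
    res.scaler.to_json(outdir / f"scaler_knn_{position}.json")
    res.cv_curve().to_csv(outdir / f"knn_cv_{position}.csv")
    res.report.to_json(outdir / f"metrics_knn_{position}.json")
    log.info("train-knn %s: k=%d acc=%.3f", position, res.chosen_k, res.report.accuracy)
    return res


def cmd_train_nn(config: RunConfig, feature_dir, outdir, position: str):
    """Tune and train the dense network for one position; persist artifacts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = _load_features(config, feature_dir, position)
    res = BodyPartNet(
        table,
        layer_range=config.nn_layer_range,
        neuron_set=config.nn_neuron_set,
        config=config.nn_config(),
        holdout_fraction=config.holdout_fraction,
        seed=config.master_seed,
        smote=config.smote(),
        scale_on_full=config.scale_on_full,
    ).fit()
    res.model.to_json(outdir / f"nn_{position}.json")
    res.scaler.to_json(outdir / f"scaler_nn_{position}.json")
    res.history.to_csv(outdir / f"nn_history_{position}.csv")
    res.grid.to_csv(outdir / f"nn_grid_{position}.csv", index=False)
    res.report.to_json(outdir / f"metrics_nn_{position}.json")
    log.info(
        "train-nn %s: %dx%d acc=%.3f",
        position,
        res.best_config.n_hidden_layers,
        res.best_config.n_neurons,
        res.report.accuracy,
    )
    return res


def cmd_evaluate(outdir, positions=("U", "N", "S")) -> dict:
    """Collect persisted per-position metrics into the comparison bundle."""
    outdir = Path(outdir)
    reports = []
    for position in positions:
        for method in ("knn", "nn"):
            mp = outdir / f"metrics_{method}_{position}.json"
            if not mp.exists():
                raise FileNotFoundError(
                    f"missing metrics {mp}; run the train stages first"
                )
            reports.append(MetricsReport.from_json(mp))
    return _bundle(reports, outdir)


def _bundle(reports: list[MetricsReport], outdir: Path) -> dict:
    table = comparison_table(reports)
    table.to_csv(outdir / "comparison.csv", index=False)
    by_method: dict[str, list[float]] = {}
    by_position: dict[str, list[float]] = {}
    for rep in reports:
        vals = [
            m[metric]
            for m in rep.per_class.values()
            for metric in ("precision", "recall", "f1")
        ]
        by_method.setdefault(rep.method, []).extend(vals)
        by_position.setdefault(rep.camera_position, []).extend(vals)
    tests = {}
    if len(by_method) >= 2:
        r = kruskal_wallis(list(by_method.values()))
        tests["method_effect"] = {"H": r.h_statistic, "df": r.df, "p": r.p_value}
    if len(by_position) >= 2:
        r = kruskal_wallis(list(by_position.values()))
        tests["position_effect"] = {"H": r.h_statistic, "df": r.df, "p": r.p_value}
    bundle = {
        "reports": {f"{r.method}_{r.camera_position}": r.to_dict() for r in reports},
        "kruskal": tests,
    }
    (outdir / "metrics.json").write_text(json.dumps(bundle, indent=1, sort_keys=True))
    return bundle


def cmd_run_all(config: RunConfig, outdir) -> dict:
    """Full experiment: simulate -> extract -> train both -> evaluate."""
    outdir = Path(outdir)
    scene_dir = outdir / "scenes"
    feat_dir = outdir / "features"
    model_dir = outdir / "models"
    cmd_simulate(config, scene_dir)
    cmd_extract(config, scene_dir, feat_dir)
    reports = []
    for position in config.positions:
        knn_res = cmd_train_knn(config, feat_dir, model_dir, position)
        nn_res = cmd_train_nn(config, feat_dir, model_dir, position)
        reports.extend([knn_res.report, nn_res.report])
        per_metric = compare_methods(knn_res.report, nn_res.report)
        for metric, r in per_metric.items():
            log.info(
                "%s %s knn-vs-nn: H=%.3f p=%.3f",
                position, metric, r.h_statistic, r.p_value,
            )
    return _bundle(reports, outdir)
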