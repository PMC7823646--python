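"""Model/Results interface for body-part classification experiments.

The two entry points mirror the familiar fit-then-results pattern of
statistical modelling packages: construct a model object from a feature
table, call :meth:`fit`, and read estimates and diagnostics off the
returned results object.

``BodyPartKNN``    tunes k over a cross-validated grid, refits on the
                   balanced training data and scores the hold-out.
``BodyPartNet``    tunes (hidden layers, neurons) by validation loss,
                   retrains the winning architecture and scores the
                   hold-out.

Both models share the protocol: a 30% stratified hold-out is split off
first; MinMax standardisation is fitted (by default on the training
portion only; optionally on the full table, mirroring a fit-before-split
order of operations) and applied everywhere; SMOTE balancing happens
strictly inside training, never touching hold-out or validation rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .balance import SmoteConfig, smote_oversample
from .classifiers import (
    KNN_K_RANGE,
    KnnGridResult,
    KnnModel,
    NnConfig,
    NnModel,
    TrainingHistory,
    knn_fit,
    knn_grid_search,
    knn_predict,
    nn_build,
    nn_grid_search,
    nn_predict,
    nn_train,
)
from .evaluate import MetricsReport
from .features import (
    FeatureTable,
    ScalerParams,
    minmax_apply,
    minmax_fit,
    split_holdout,
)


class _BaseBodyPartModel:
    """Shared hold-out / standardisation plumbing."""

    def __init__(
        self,
        table: FeatureTable,
        holdout_fraction: float = 0.3,
        seed: int = 0,
        smote: SmoteConfig | None = None,
        scale_on_full: bool = False,
    ):
        self.table = table
        self.holdout_fraction = holdout_fraction
        self.seed = seed
        self.smote = smote or SmoteConfig(seed=seed + 3)
        self.scale_on_full = scale_on_full

    def _prepare(self) -> tuple[FeatureTable, FeatureTable, ScalerParams]:
        train, holdout = split_holdout(
            self.table, self.holdout_fraction, seed=self.seed + 1
        )
        scaler = minmax_fit(self.table if self.scale_on_full else train)
        return minmax_apply(train, scaler), minmax_apply(holdout, scaler), scaler


@dataclass
class BodyPartKNNResults:
    """Chosen k, CV curve, fitted model and hold-out metrics."""

    model: KnnModel
    grid: KnnGridResult
    scaler: ScalerParams
    report: MetricsReport
    class_names: tuple[str, ...]

    @property
    def chosen_k(self) -> int:
        return self.grid.chosen_k

    def predict(self, table: FeatureTable) -> np.ndarray:
        """Class indices for a raw (unstandardised) feature table."""
        return knn_predict(self.model, minmax_apply(table, self.scaler).X)

    def cv_curve(self) -> pd.Series:
        return self.grid.as_series()

    def summary(self) -> str:
        lines = [
            "Body-part kNN classification",
            "============================",
            f"chosen k: {self.chosen_k} "
            f"(grid {min(self.grid.mean_accuracy)}..{max(self.grid.mean_accuracy)}, "
            f"mean CV accuracy {self.grid.mean_accuracy[self.chosen_k]:.3f})",
            "",
            self.report.summary(),
        ]
        return "\n".join(lines)


class BodyPartKNN(_BaseBodyPartModel):
    """k-nearest-neighbour body-part classifier with tuned k.

    Parameters
    ----------
    table
        Raw feature table (one camera position).
    holdout_fraction
        Fraction split off before any tuning (default 0.3).
    seed
        Master seed; all internal randomness derives from it.
    smote
        Balancing settings applied inside CV folds and the final fit.
    scale_on_full
        Fit the MinMax scaler on the full table before splitting instead
        of on the training portion only.
    """

    def fit(self, ks=KNN_K_RANGE, folds: int = 5) -> BodyPartKNNResults:
        train, holdout, scaler = self._prepare()
        grid = knn_grid_search(
            train, ks=ks, folds=folds, seed=self.seed + 2, smote=self.smote
        )
        Xb, yb = smote_oversample(train.X, train.y, self.smote)
        model = knn_fit(Xb, yb, grid.chosen_k)
        y_pred = knn_predict(model, holdout.X)
        report = MetricsReport.from_predictions(
            holdout.y,
            y_pred,
            train.class_names,
            method="knn",
            camera_position=train.camera_position or "",
        )
        return BodyPartKNNResults(model, grid, scaler, report, train.class_names)


@dataclass
class BodyPartNetResults:
    """Winning architecture, its training history and hold-out metrics."""

    model: NnModel
    best_config: NnConfig
    grid: pd.DataFrame
    history: TrainingHistory
    scaler: ScalerParams
    report: MetricsReport
    class_names: tuple[str, ...]

    def predict(self, table: FeatureTable) -> np.ndarray:
        labels, _ = nn_predict(self.model, minmax_apply(table, self.scaler).X)
        return labels

    def predict_proba(self, table: FeatureTable) -> np.ndarray:
        _, probs = nn_predict(self.model, minmax_apply(table, self.scaler).X)
        return probs

    def summary(self) -> str:
        lines = [
            "Body-part dense-network classification",
            "======================================",
            f"architecture: {self.best_config.n_hidden_layers} hidden layer(s) "
            f"x {self.best_config.n_neurons} neurons "
            f"(best epoch {self.history.best_epoch}, "
            f"stopped after {self.history.stopped_epoch})",
            "",
            self.report.summary(),
        ]
        return "\n".join(lines)


class BodyPartNet(_BaseBodyPartModel):
    """Dense feed-forward body-part classifier with tuned depth/width.

    ``layer_range`` and ``neuron_set`` define the architecture grid; the
    full original grid (17 x 7 = 119 cells) is available through
    :data:`cowseg.classifiers.NN_HIDDEN_LAYER_RANGE` and
    :data:`cowseg.classifiers.NN_NEURON_SET`.
    """

    def __init__(
        self,
        table: FeatureTable,
        layer_range=(0, 1, 2),
        neuron_set=(10, 50),
        config: NnConfig | None = None,
        **kwargs,
    ):
        super().__init__(table, **kwargs)
        self.layer_range = tuple(layer_range)
        self.neuron_set = tuple(neuron_set)
        self.config = config or NnConfig(seed=self.seed + 4)

    def fit(self) -> BodyPartNetResults:
        train, holdout, scaler = self._prepare()
        best_cfg, grid = nn_grid_search(
            train, self.layer_range, self.neuron_set, self.config
        )
        model = nn_build(best_cfg, train.n_classes)
        model, history = nn_train(model, train, best_cfg, smote=self.smote)
        y_pred, _ = nn_predict(model, holdout.X)
        report = MetricsReport.from_predictions(
            holdout.y,
            y_pred,
            train.class_names,
            method="nn",
            camera_position=train.camera_position or "",
        )
        return BodyPartNetResults(
            model, best_cfg, grid, history, scaler, report, train.class_names
        )
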