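"""The two supervised learners: kNN and a dense feed-forward network.

kNN stores the (standardised) training rows verbatim and classifies a
query by majority vote among its k nearest Euclidean neighbours.  The
hyperparameter k is tuned by grid search over k = 1..20 with five-fold
cross-validation, balancing each fold's training part with SMOTE and
scoring accuracy on the untouched fifth; equal mean accuracies resolve to
the smallest k.  Tie rules at prediction time are fully deterministic:
vote ties go to the class of the nearest neighbour among the tied
classes, and exact distance ties are ordered by stored-row index.

The network is a plain stack of dense ReLU layers (5 inputs, one output
node per body part, softmax), with 15% dropout after every second hidden
layer, trained by mini-batch Adam on categorical cross entropy with a
linearly decaying learning rate and early stopping (patience 5) on the
validation loss.  Depth and width are tuned over a (layers x neurons)
grid by smallest validation loss.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.model_selection import KFold, StratifiedKFold, train_test_split

from .balance import SmoteConfig, smote_oversample
from .exceptions import (
    InvalidParameterError,
    ShapeError,
    TrainingFailureError,
)
from .features import FeatureTable

#: The full hyperparameter grids used in the original tuning protocol.
KNN_K_RANGE = tuple(range(1, 21))
NN_HIDDEN_LAYER_RANGE = tuple(range(0, 17))
NN_NEURON_SET = (10, 50, 100, 150, 200, 250, 300)


def full_nn_grid() -> list[tuple[int, int]]:
    """All (hidden layers, neurons) pairs of the full tuning grid."""
    return [(nl, nn) for nl in NN_HIDDEN_LAYER_RANGE for nn in NN_NEURON_SET]


# ---------------------------------------------------------------------------
# k nearest neighbours
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KnnModel:
    """Stored-exemplar classifier: training data kept verbatim plus k."""

    X: np.ndarray
    y: np.ndarray
    k: int

    def __post_init__(self):
        object.__setattr__(self, "X", np.asarray(self.X, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y))

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {"k": self.k, "X": self.X.tolist(), "y": self.y.tolist()}
            )
        )

    @classmethod
    def from_json(cls, path) -> "KnnModel":
        d = json.loads(Path(path).read_text())
        return cls(np.array(d["X"]), np.array(d["y"]), d["k"])


def knn_fit(features, labels, k: int) -> KnnModel:
    """Store the training data; k must satisfy 1 <= k <= n samples."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or len(X) != len(y):
        raise ShapeError("features must be 2-D with one label per row")
    if not 1 <= k <= len(X):
        raise InvalidParameterError(f"k must be in [1, {len(X)}], got {k}")
    return KnnModel(X.copy(), y.copy(), int(k))


# brute force is exact on distance ties; the KD-tree path is used once
# the distance matrix would get large
_BRUTE_FORCE_LIMIT = 5_000_000


def _neighbor_labels(
    trainX: np.ndarray, trainy: np.ndarray, queries: np.ndarray, k: int
) -> np.ndarray:
    """Labels of the k nearest training rows per query, nearest first.

    Ordering is by (distance, stored-row index), so exact distance ties
    resolve to the lower index.
    """
    n_train, n_query = len(trainX), len(queries)
    if n_train * n_query <= _BRUTE_FORCE_LIMIT:
        d2 = ((queries[:, None, :] - trainX[None, :, :]) ** 2).sum(-1)
        idx = np.argsort(d2, axis=1, kind="stable")[:, :k]
        return trainy[idx]
    tree = cKDTree(trainX)
    dist, idx = tree.query(queries, k=k, workers=1)
    if k == 1:
        return trainy[idx[:, None]]
    # enforce (distance, index) order within the returned neighbour sets
    order = np.lexsort((idx, dist), axis=1)
    idx = np.take_along_axis(idx, order, axis=1)
    return trainy[idx]


def _vote(neigh_labels: np.ndarray, n_classes: int) -> np.ndarray:
    """Majority vote per row; ties go to the nearest tied-class neighbour."""
    nq, k = neigh_labels.shape
    votes = np.zeros((nq, n_classes), dtype=np.int32)
    rows = np.arange(nq)
    for j in range(k):
        votes[rows, neigh_labels[:, j]] += 1
    tied = votes == votes.max(axis=1, keepdims=True)
    out = np.full(nq, -1, dtype=neigh_labels.dtype)
    open_rows = np.ones(nq, dtype=bool)
    for j in range(k):
        lab = neigh_labels[:, j]
        sel = open_rows & tied[rows, lab]
        out[sel] = lab[sel]
        open_rows &= ~sel
        if not open_rows.any():
            break
    return out


def knn_predict(model: KnnModel, queries) -> np.ndarray:
    """Classify queries by k-nearest-neighbour majority vote."""
    Q = np.atleast_2d(np.asarray(queries, dtype=float))
    if Q.shape[1] != model.X.shape[1]:
        raise ShapeError(
            f"queries have {Q.shape[1]} features, model stores {model.X.shape[1]}"
        )
    # class indices may be arbitrary labels; recode to 0..C-1 for voting
    classes, ycode = np.unique(model.y, return_inverse=True)
    neigh = _neighbor_labels(model.X, ycode, Q, model.k)
    return classes[_vote(neigh, len(classes))]


@dataclass
class KnnGridResult:
    """Mean CV accuracy per k and the selected (smallest argmax) k."""

    mean_accuracy: dict[int, float]
    chosen_k: int

    def as_series(self) -> pd.Series:
        return pd.Series(self.mean_accuracy, name="mean_cv_accuracy")


def choose_k(mean_accuracy: dict[int, float]) -> int:
    """Smallest k attaining the maximal mean accuracy."""
    best = max(mean_accuracy.values())
    return min(k for k, a in mean_accuracy.items() if a == best)


def knn_grid_search(
    train: FeatureTable,
    ks=KNN_K_RANGE,
    folds: int = 5,
    seed: int = 0,
    smote: SmoteConfig | None = None,
) -> KnnGridResult:
    """Cross-validated grid search for k.

    The training table is split into ``folds`` random equal parts; per
    fold, SMOTE balances the other folds' rows (never the held-out part),
    a kNN model is fitted and scored by accuracy on the held-out part.
    The per-k accuracies are averaged over folds and the smallest k
    maximising the average wins.  All randomness derives from ``seed``.
    """
    ks = list(ks)
    if not ks or min(ks) < 1:
        raise InvalidParameterError("ks must be positive integers")
    X, y = train.X, train.y
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise InvalidParameterError(
            f"every class needs >= {folds} samples for {folds}-fold CV"
        )
    smote = smote or SmoteConfig()

    splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(splitter.split(X))
    n_classes = len(np.unique(y))
    if any(len(np.unique(y[tr])) < n_classes for tr, _ in splits):
        warnings.warn(
            "a class is absent from some training fold; re-splitting stratified",
            stacklevel=2,
        )
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = list(splitter.split(X, y))

    kmax = max(ks)
    acc = {k: [] for k in ks}
    for i, (tr, te) in enumerate(splits):
        Xb, yb = smote_oversample(
            X[tr], y[tr], replace(smote, seed=smote.seed + 7919 * i)
        )
        kk = min(kmax, len(Xb))
        neigh = _neighbor_labels(Xb, yb, X[te], kk)
        for k in ks:
            pred = _vote(neigh[:, : min(k, kk)], n_classes)
            acc[k].append(float(np.mean(pred == y[te])))
    mean_acc = {k: float(np.mean(v)) for k, v in acc.items()}
    return KnnGridResult(mean_acc, choose_k(mean_acc))


# ---------------------------------------------------------------------------
# Dense feed-forward network
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NnConfig:
    """Architecture and training settings of the dense network."""

    n_hidden_layers: int = 1
    n_neurons: int = 50
    dropout_rate: float = 0.15
    dropout_every: int = 2
    learning_rate: float = 0.001
    max_epochs: int = 100
    batch_size: int = 256
    early_stop_patience: int = 5
    val_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.n_hidden_layers <= 16:
            raise InvalidParameterError("n_hidden_layers must be in 0..16")
        if self.n_neurons < 1:
            raise InvalidParameterError("n_neurons must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise InvalidParameterError("dropout_rate must be in [0, 1)")
        if not 0.0 < self.val_fraction < 1.0:
            raise InvalidParameterError("val_fraction must be in (0, 1)")
        if self.max_epochs < 1 or self.batch_size < 1:
            raise InvalidParameterError("max_epochs and batch_size must be >= 1")


@dataclass
class NnModel:
    """Weights of the dense stack: 5 -> hidden layers -> softmax output."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    config: NnConfig
    n_classes: int

    @property
    def layer_sizes(self) -> list[int]:
        return [self.weights[0].shape[0]] + [W.shape[1] for W in self.weights]

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "n_classes": self.n_classes,
                    "config": self.config.__dict__,
                    "weights": [W.tolist() for W in self.weights],
                    "biases": [b.tolist() for b in self.biases],
                }
            )
        )

    @classmethod
    def from_json(cls, path) -> "NnModel":
        d = json.loads(Path(path).read_text())
        return cls(
            [np.array(W) for W in d["weights"]],
            [np.array(b) for b in d["biases"]],
            NnConfig(**d["config"]),
            d["n_classes"],
        )


@dataclass
class TrainingHistory:
    """Per-epoch losses and the early-stopping bookkeeping (1-indexed)."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "epoch": np.arange(1, len(self.train_loss) + 1),
                "train_loss": self.train_loss,
                "val_loss": self.val_loss,
            }
        ).to_csv(path, index=False)


class EarlyStopper:
    """Stop after ``patience`` epochs without validation improvement."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best_epoch = 0
        self.best_loss = np.inf

    def update(self, epoch: int, val_loss: float) -> bool:
        """Record epoch's validation loss; return True to stop."""
        if val_loss < self.best_loss:
            self.best_loss = val_loss
            self.best_epoch = epoch
        return epoch - self.best_epoch >= self.patience


def stopping_epoch(val_losses, patience: int) -> int:
    """Epoch at which training stops for a given validation-loss trace."""
    stopper = EarlyStopper(patience)
    for e, v in enumerate(val_losses, start=1):
        if stopper.update(e, v):
            return e
    return len(val_losses)


def nn_build(config: NnConfig, n_classes: int) -> NnModel:
    """Initialise the dense stack with seeded Glorot-uniform weights.

    Zero hidden layers degenerates to multinomial logistic regression
    (a single 5 -> n_classes softmax layer).
    """
    if n_classes < 2:
        raise InvalidParameterError("need at least 2 classes")
    sizes = [5] + [config.n_neurons] * config.n_hidden_layers + [n_classes]
    rng = np.random.default_rng(config.seed)
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return NnModel(weights, biases, config, n_classes)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward(model: NnModel, X, rng=None):
    """Forward pass; with ``rng`` set, inverted dropout masks are applied
    after every ``dropout_every``-th hidden layer (training mode)."""
    cfg = model.config
    acts = [X]
    masks = [None]
    h = X
    n_hidden = len(model.weights) - 1
    for i in range(n_hidden):
        h = np.maximum(h @ model.weights[i] + model.biases[i], 0.0)
        mask = None
        if rng is not None and cfg.dropout_rate > 0 and (i + 1) % cfg.dropout_every == 0:
            mask = (rng.random(h.shape) >= cfg.dropout_rate) / (1.0 - cfg.dropout_rate)
            h = h * mask
        acts.append(h)
        masks.append(mask)
    probs = _softmax(h @ model.weights[-1] + model.biases[-1])
    return probs, acts, masks


def _cross_entropy(probs: np.ndarray, onehot: np.ndarray) -> float:
    return float(-np.mean(np.sum(onehot * np.log(probs + 1e-12), axis=1)))


def nn_predict(model: NnModel, queries) -> tuple[np.ndarray, np.ndarray]:
    """Class labels (argmax, lowest index on ties) and probability rows."""
    Q = np.atleast_2d(np.asarray(queries, dtype=float))
    if Q.shape[1] != model.weights[0].shape[0]:
        raise ShapeError(
            f"queries have {Q.shape[1]} features, model expects "
            f"{model.weights[0].shape[0]}"
        )
    probs, _, _ = _forward(model, Q)
    return probs.argmax(axis=1), probs


def nn_train(
    model: NnModel,
    train: FeatureTable,
    config: NnConfig | None = None,
    smote: SmoteConfig | None = None,
) -> tuple[NnModel, TrainingHistory]:
    """Train the network on a (standardised) feature table.

    30% of the rows are split off for validation before any balancing;
    SMOTE is applied to the remaining 70% only.  Mini-batch Adam on
    categorical cross entropy, learning rate decaying linearly from lr0
    to a floor of lr0/100, early stopping with the configured patience;
    the returned model carries the best-epoch weights.
    """
    cfg = config or model.config
    X, y = train.X, train.y
    if len(X) == 0:
        raise InvalidParameterError("training table is empty")
    n_classes = model.n_classes
    if train.n_classes != n_classes:
        raise ShapeError(
            f"table has {train.n_classes} classes, model outputs {n_classes}"
        )
    seed = cfg.seed % (2**31)
    stratify = y if np.unique(y, return_counts=True)[1].min() >= 2 else None
    X_tr, X_val, y_tr, y_val = train_test_split(
        X, y, test_size=cfg.val_fraction, random_state=seed, stratify=stratify
    )
    if len(np.unique(y_tr)) > 1:
        X_tr, y_tr = smote_oversample(
            X_tr, y_tr, smote or SmoteConfig(seed=seed + 1)
        )
    onehot_tr = np.eye(n_classes)[y_tr]
    onehot_val = np.eye(n_classes)[y_val]

    rng = np.random.default_rng(seed + 2)
    weights = [W.copy() for W in model.weights]
    biases = [b.copy() for b in model.biases]
    work = NnModel(weights, biases, cfg, n_classes)
    # Adam state
    m_w = [np.zeros_like(W) for W in weights]
    v_w = [np.zeros_like(W) for W in weights]
    m_b = [np.zeros_like(b) for b in biases]
    v_b = [np.zeros_like(b) for b in biases]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    history = TrainingHistory()
    stopper = EarlyStopper(cfg.early_stop_patience)
    best_weights = [W.copy() for W in weights]
    best_biases = [b.copy() for b in biases]
    n = len(X_tr)

    for epoch in range(1, cfg.max_epochs + 1):
        lr = max(
            cfg.learning_rate * (1.0 - (epoch - 1) / cfg.max_epochs),
            cfg.learning_rate / 100.0,
        )
        order = rng.permutation(n)
        batch_losses = []
        for start in range(0, n, cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            xb, yb = X_tr[sel], onehot_tr[sel]
            probs, acts, masks = _forward(work, xb, rng=rng)
            loss = _cross_entropy(probs, yb)
            batch_losses.append(loss)
            if not np.isfinite(loss):
                history.stopped_epoch = epoch
                raise TrainingFailureError(
                    f"loss diverged at epoch {epoch}", history=history
                )
            # backprop
            delta = (probs - yb) / len(xb)
            grads_w, grads_b = [None] * len(weights), [None] * len(weights)
            for i in range(len(weights) - 1, -1, -1):
                grads_w[i] = acts[i].T @ delta
                grads_b[i] = delta.sum(axis=0)
                if i > 0:
                    delta = delta @ weights[i].T
                    if masks[i] is not None:
                        delta = delta * masks[i]
                    delta = delta * (acts[i] > 0)
            step += 1
            bc1 = 1.0 - beta1**step
            bc2 = 1.0 - beta2**step
            for i in range(len(weights)):
                m_w[i] = beta1 * m_w[i] + (1 - beta1) * grads_w[i]
                v_w[i] = beta2 * v_w[i] + (1 - beta2) * grads_w[i] ** 2
                weights[i] -= lr * (m_w[i] / bc1) / (np.sqrt(v_w[i] / bc2) + eps)
                m_b[i] = beta1 * m_b[i] + (1 - beta1) * grads_b[i]
                v_b[i] = beta2 * v_b[i] + (1 - beta2) * grads_b[i] ** 2
                biases[i] -= lr * (m_b[i] / bc1) / (np.sqrt(v_b[i] / bc2) + eps)

        val_probs, _, _ = _forward(work, X_val)
        val_loss = _cross_entropy(val_probs, onehot_val)
        history.train_loss.append(float(np.mean(batch_losses)))
        history.val_loss.append(val_loss)
        improved = val_loss < stopper.best_loss
        stop = stopper.update(epoch, val_loss)
        if improved:
            best_weights = [W.copy() for W in weights]
            best_biases = [b.copy() for b in biases]
        if stop:
            break

    history.stopped_epoch = len(history.val_loss)
    history.best_epoch = stopper.best_epoch
    return NnModel(best_weights, best_biases, cfg, n_classes), history


def nn_grid_search(
    train: FeatureTable,
    layer_range=(0, 1, 2),
    neuron_set=(10, 50),
    config: NnConfig | None = None,
) -> tuple[NnConfig, pd.DataFrame]:
    """Train one network per (layers, neurons) pair; smallest best
    validation loss wins, ties to fewer layers then fewer neurons.

    Returns the winning config and a tidy per-cell results frame
    (columns: n_hidden_layers, n_neurons, val_loss, best_epoch, status).
    """
    base = config or NnConfig()
    cells = []
    best_cfg, best_loss = None, np.inf
    for nl in layer_range:
        for nn in neuron_set:
            cfg = replace(base, n_hidden_layers=nl, n_neurons=nn)
            try:
                model = nn_build(cfg, train.n_classes)
                _, hist = nn_train(model, train, cfg)
                loss = float(np.min(hist.val_loss))
                cells.append((nl, nn, loss, hist.best_epoch, "ok"))
                if loss < best_loss:
                    best_loss, best_cfg = loss, cfg
            except TrainingFailureError:
                cells.append((nl, nn, np.nan, 0, "diverged"))
    if best_cfg is None:
        raise TrainingFailureError("every grid cell diverged")
    frame = pd.DataFrame(
        cells,
        columns=["n_hidden_layers", "n_neurons", "val_loss", "best_epoch", "status"],
    )
    return best_cfg, frame
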