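"""Class balancing by synthetic minority oversampling (SMOTE).

Body parts cover very unequal pixel areas (legs and udder are small, back
and rump large), so training tables are heavily unbalanced.  SMOTE
equalises class counts by interpolating between an existing minority
sample x_i and one of its k nearest same-class neighbours x_j:

    x_new = x_i + lambda * (x_j - x_i),   lambda ~ Uniform[0, 1].

Synthetic points therefore never leave the convex hull of their class.
Oversampling must happen strictly after any train/validation/fold split:
a synthetic point is a function of real training points, and letting it
cross into evaluation data leaks training information.  The pipeline
enforces this ordering structurally (balancing lives inside the fold and
validation loops).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .exceptions import EmptyInputError, InsufficientClassSizeError, InvalidParameterError


@dataclass(frozen=True)
class SmoteConfig:
    """SMOTE settings: neighbourhood size, seed, optional target count.

    ``target`` defaults to the majority-class count; it may only be set
    at or above the current maximum class count.
    """

    k_neighbors: int = 5
    seed: int = 0
    target: int | None = None

    def __post_init__(self):
        if self.k_neighbors < 1:
            raise InvalidParameterError("k_neighbors must be >= 1")


def smote_oversample(
    features: np.ndarray,
    labels: np.ndarray,
    config: SmoteConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Oversample every class to the target count.

    Original rows are preserved unchanged and come first in the output;
    synthetic rows follow, grouped by class in label order.  Deterministic
    for a fixed seed.
    """
    config = config or SmoteConfig()
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.size == 0 or len(y) == 0:
        raise EmptyInputError("cannot oversample an empty data set")
    if X.ndim != 2 or len(X) != len(y):
        raise InvalidParameterError("features must be 2-D with one label per row")

    classes, counts = np.unique(y, return_counts=True)
    target = int(config.target) if config.target is not None else int(counts.max())
    if target < counts.max():
        raise InvalidParameterError("target must be >= the majority class count")

    rng = np.random.default_rng(config.seed)
    new_X, new_y = [], []
    for cls, count in zip(classes, counts):
        n_needed = target - int(count)
        if n_needed == 0:
            continue
        if count < 2:
            raise InsufficientClassSizeError(
                f"class {cls!r} has {count} sample(s); SMOTE needs >= 2"
            )
        Xc = X[y == cls]
        k = min(config.k_neighbors, int(count) - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Xc)
        # drop the self-neighbour in column 0
        neigh = nn.kneighbors(Xc, return_distance=False)[:, 1:]
        base = rng.integers(0, len(Xc), size=n_needed)
        pick = rng.integers(0, k, size=n_needed)
        lam = rng.uniform(0.0, 1.0, size=n_needed)
        xi = Xc[base]
        xj = Xc[neigh[base, pick]]
        new_X.append(xi + lam[:, None] * (xj - xi))
        new_y.append(np.full(n_needed, cls, dtype=y.dtype))

    if not new_X:
        return X.copy(), y.copy()
    return np.vstack([X] + new_X), np.concatenate([y] + new_y)
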