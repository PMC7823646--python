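"""Pixel-property features for body-part classification.

Every labelled foreground pixel of a depth scene contributes one row of
five predictors — row index, column index, depth (mm), mean curvature of
the depth surface and local depth variance — plus a one-hot body-part
response.  Curvature and variance are computed from the nine-pixel square
(3x3 neighbourhood) around the pixel: central differences give the
gradient g (mm/pixel) and Hessian H (mm/pixel^2) of the depth surface,
and the mean curvature score is

    m_curv = (g H g^T - |g|^2 Trace(H)) / (2 |g|^3)

with the convention m_curv = 0 where |g| = 0 (the expression is 0/0 on a
locally flat patch).  Depth stays in raw millimetres against the pixel
grid; the mixed units wash out in the MinMax standardisation applied
before any learning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from scipy.ndimage import convolve, minimum_filter
from shapely.geometry import Polygon
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import MinMaxScaler

from .exceptions import (
    EmptyInputError,
    IncompletePatchError,
    InvalidParameterError,
    InvalidPolygonError,
)
from .scene_sim import BODY_PARTS, PART_INDEX, DepthScene

#: Predictor column names, in feature-table order.
FEATURE_COLUMNS = ("row", "col", "depth", "m_curv", "var")

#: Full CSV header (running index + predictors + one-hot responses).
CSV_COLUMNS = ("No",) + FEATURE_COLUMNS + BODY_PARTS


# ---------------------------------------------------------------------------
# 3x3 patch operations
# ---------------------------------------------------------------------------

def _check_patch(patch) -> np.ndarray:
    patch = np.asarray(patch, dtype=float)
    if patch.shape != (3, 3):
        raise InvalidParameterError("patch must be 3x3")
    if np.any(patch <= 0):
        raise IncompletePatchError("patch contains background (zero) pixels")
    return patch


def gradient_hessian(patch) -> tuple[np.ndarray, np.ndarray]:
    """Central-difference gradient and Hessian of a 3x3 depth patch.

    Unit pixel spacing; g = (df/dcol, df/drow); H is symmetric with the
    off-diagonal from the four-corner cross difference.  Exact for
    surfaces of polynomial degree <= 2.
    """
    f = _check_patch(patch)
    gx = (f[1, 2] - f[1, 0]) / 2.0
    gy = (f[2, 1] - f[0, 1]) / 2.0
    hxx = f[1, 2] - 2.0 * f[1, 1] + f[1, 0]
    hyy = f[2, 1] - 2.0 * f[1, 1] + f[0, 1]
    hxy = (f[2, 2] - f[2, 0] - f[0, 2] + f[0, 0]) / 4.0
    return np.array([gx, gy]), np.array([[hxx, hxy], [hxy, hyy]])


def mean_curvature(g, H) -> float:
    """Mean-curvature score from gradient and Hessian; 0 where |g| = 0."""
    g = np.asarray(g, dtype=float)
    H = np.asarray(H, dtype=float)
    norm = np.linalg.norm(g)
    if norm == 0.0:
        return 0.0
    return float((g @ H @ g - norm**2 * np.trace(H)) / (2.0 * norm**3))


def local_variance(patch) -> float:
    """Sample variance (denominator n-1 = 8) of the nine patch values."""
    f = _check_patch(patch)
    return float(np.var(f, ddof=1))


# ---------------------------------------------------------------------------
# Polygon labelling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PolygonLabel:
    """A labelling polygon: (row, col) vertices and a body-part code."""

    vertices: tuple[tuple[float, float], ...]
    part_label: str

    def __post_init__(self):
        if len(self.vertices) < 3:
            raise InvalidPolygonError("polygon needs at least 3 vertices")
        if self.part_label not in BODY_PARTS:
            raise InvalidParameterError(f"unknown part label {self.part_label!r}")


def label_by_polygons(height: int, width: int, polygons) -> np.ndarray:
    """Rasterise labelling polygons into a label mask.

    Pixels strictly inside a polygon get that polygon's part index;
    overlaps are resolved by list order (later polygons win); everything
    else is 0.  Mirrors a manual workflow of clicking polygons around the
    body parts, replaced here by point-in-polygon rasterisation.
    """
    mask = np.zeros((height, width), dtype=np.uint8)
    if not polygons:
        return mask
    cols, rows = np.meshgrid(np.arange(width), np.arange(height))
    pts_r, pts_c = rows.ravel().astype(float), cols.ravel().astype(float)
    for poly in polygons:
        shp = Polygon([(c, r) for r, c in poly.vertices])
        if not shp.is_valid:  # self-intersecting input: even-odd repair
            shp = shp.buffer(0)
        inside = shapely.contains_xy(shp, pts_c, pts_r).reshape(height, width)
        mask[inside] = PART_INDEX[poly.part_label]
    return mask


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Predictors plus one-hot responses for one camera position.

    ``df`` carries the columns row, col, depth, m_curv, var and the eight
    one-hot body-part indicators (He..Ud); for camera position 'U' the Ud
    column is identically zero and ``n_classes`` is 7.
    """

    df: pd.DataFrame
    camera_position: str | None = None

    def __post_init__(self):
        missing = [c for c in FEATURE_COLUMNS + BODY_PARTS if c not in self.df]
        if missing:
            raise InvalidParameterError(f"feature table missing columns {missing}")
        if self.camera_position == "U" and len(self.df) and self.df["Ud"].any():
            raise InvalidParameterError("position U tables must not contain Ud")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def class_names(self) -> tuple[str, ...]:
        return BODY_PARTS[:7] if self.camera_position == "U" else BODY_PARTS

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def X(self) -> np.ndarray:
        """Predictor matrix, shape (n, 5), float64."""
        return self.df[list(FEATURE_COLUMNS)].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        """Class indices (0-based into :attr:`class_names`)."""
        onehot = self.df[list(self.class_names)].to_numpy()
        return onehot.argmax(axis=1)

    @property
    def y_onehot(self) -> np.ndarray:
        return self.df[list(self.class_names)].to_numpy(dtype=int)

    def replace_features(self, X: np.ndarray) -> "FeatureTable":
        df = self.df.copy()
        df[list(FEATURE_COLUMNS)] = X
        return FeatureTable(df, self.camera_position)

    def to_csv(self, path) -> None:
        """Write with the canonical header; m_curv/var printed to 2 and 4
        decimals (the table convention for these columns)."""
        out = self.df.copy()
        out.insert(0, "No", np.arange(len(out)))
        out["m_curv"] = out["m_curv"].map(lambda v: f"{v:.2f}")
        out["var"] = out["var"].map(lambda v: f"{v:.4f}")
        out.to_csv(path, index=False, columns=list(CSV_COLUMNS))

    @classmethod
    def from_csv(cls, path, camera_position=None) -> "FeatureTable":
        df = pd.read_csv(path)
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise InvalidParameterError(f"CSV missing columns {missing}")
        return cls(df.drop(columns=["No"]), camera_position)


def extract_features(
    scene: DepthScene,
    camera_position: str | None = None,
    max_rows: int | None = None,
    seed: int = 0,
) -> FeatureTable:
    """Build the feature table of a labelled depth scene.

    One row per labelled foreground pixel whose full 3x3 neighbourhood is
    foreground and inside the image (patches touching background or the
    border would mix the zeroed background into curvature and variance,
    so those pixels are skipped).  ``max_rows`` takes a seeded uniform
    subsample, used to keep desk-scale experiments tractable.
    """
    depth = scene.depth.astype(float)
    labels = scene.labels
    fg = depth > 0
    eligible = minimum_filter(fg, size=3, mode="constant", cval=False)
    eligible &= labels > 0
    if camera_position is None and scene.pose is not None:
        camera_position = scene.pose.preset

    r_idx, c_idx = np.nonzero(eligible)
    if len(r_idx) == 0:
        df = pd.DataFrame(
            {c: np.array([], dtype=float) for c in FEATURE_COLUMNS}
            | {p: np.array([], dtype=int) for p in BODY_PARTS}
        )
        return FeatureTable(df, camera_position)

    # whole-image central differences (identical to the per-patch ops)
    gx = np.zeros_like(depth)
    gy = np.zeros_like(depth)
    gx[:, 1:-1] = (depth[:, 2:] - depth[:, :-2]) / 2.0
    gy[1:-1, :] = (depth[2:, :] - depth[:-2, :]) / 2.0
    hxx = np.zeros_like(depth)
    hyy = np.zeros_like(depth)
    hxy = np.zeros_like(depth)
    hxx[:, 1:-1] = depth[:, 2:] - 2 * depth[:, 1:-1] + depth[:, :-2]
    hyy[1:-1, :] = depth[2:, :] - 2 * depth[1:-1, :] + depth[:-2, :]
    hxy[1:-1, 1:-1] = (
        depth[2:, 2:] - depth[2:, :-2] - depth[:-2, 2:] + depth[:-2, :-2]
    ) / 4.0

    g2 = gx**2 + gy**2
    gnorm = np.sqrt(g2)
    ghg = gx * (hxx * gx + hxy * gy) + gy * (hxy * gx + hyy * gy)
    with np.errstate(divide="ignore", invalid="ignore"):
        mc = np.where(
            gnorm > 0, (ghg - g2 * (hxx + hyy)) / (2.0 * gnorm**3), 0.0
        )

    # 3x3 sample variance via sliding sums
    ones = np.ones((3, 3))
    s1 = convolve(depth, ones, mode="constant", cval=0.0)
    s2 = convolve(depth**2, ones, mode="constant", cval=0.0)
    var = (s2 - s1**2 / 9.0) / 8.0
    var = np.maximum(var, 0.0)

    if max_rows is not None and len(r_idx) > max_rows:
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(r_idx), size=max_rows, replace=False)
        keep.sort()
        r_idx, c_idx = r_idx[keep], c_idx[keep]

    lab = labels[r_idx, c_idx]
    data = {
        "row": r_idx.astype(float),
        "col": c_idx.astype(float),
        "depth": depth[r_idx, c_idx],
        "m_curv": mc[r_idx, c_idx],
        "var": var[r_idx, c_idx],
    }
    for i, part in enumerate(BODY_PARTS):
        data[part] = (lab == i + 1).astype(int)
    return FeatureTable(pd.DataFrame(data), camera_position)


# ---------------------------------------------------------------------------
# Standardisation and splitting
# ---------------------------------------------------------------------------

@dataclass
class ScalerParams:
    """Per-feature minima and maxima of the fitting data."""

    minimum: np.ndarray
    maximum: np.ndarray

    def __post_init__(self):
        self.minimum = np.asarray(self.minimum, dtype=float)
        self.maximum = np.asarray(self.maximum, dtype=float)
        if np.any(self.maximum < self.minimum):
            raise InvalidParameterError("max must be >= min per feature")

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "features": list(FEATURE_COLUMNS),
                    "min": self.minimum.tolist(),
                    "max": self.maximum.tolist(),
                }
            )
        )

    @classmethod
    def from_json(cls, path) -> "ScalerParams":
        d = json.loads(Path(path).read_text())
        return cls(np.array(d["min"]), np.array(d["max"]))


def minmax_fit(table: FeatureTable) -> ScalerParams:
    """Fit MinMax standardisation parameters on a feature table."""
    if len(table) == 0:
        raise EmptyInputError("cannot fit a scaler on an empty table")
    scaler = MinMaxScaler().fit(table.X)
    return ScalerParams(scaler.data_min_, scaler.data_max_)


def minmax_apply(table: FeatureTable, params: ScalerParams) -> FeatureTable:
    """Map each feature to (x - min) / (max - min); no clipping.

    A constant feature (max == min) maps to 0.  Values outside the fitted
    range map outside [0, 1] — unseen data is not clipped.
    """
    span = params.maximum - params.minimum
    span = np.where(span == 0, 1.0, span)
    return table.replace_features((table.X - params.minimum) / span)


def split_holdout(
    table: FeatureTable,
    fraction: float = 0.3,
    seed: int = 0,
    stratified: bool = True,
) -> tuple[FeatureTable, FeatureTable]:
    """Split off a hold-out set (default 30%), disjoint and exhaustive."""
    if not 0.0 < fraction < 1.0:
        raise InvalidParameterError("fraction must be in (0, 1)")
    if len(table) == 0:
        raise EmptyInputError("cannot split an empty table")
    idx = np.arange(len(table))
    strat = table.y if stratified else None
    train_idx, hold_idx = train_test_split(
        idx, test_size=fraction, random_state=seed, stratify=strat
    )
    pos = table.camera_position
    return (
        FeatureTable(table.df.iloc[np.sort(train_idx)].reset_index(drop=True), pos),
        FeatureTable(table.df.iloc[np.sort(hold_idx)].reset_index(drop=True), pos),
    )
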