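"""Synthetic labelled depth scenes of a walking dairy cow.

The recording unit this package emulates observed Holstein Friesian cows
walking through a passage, from three Kinect V1 viewpoints: a side-view
camera 0.6 m above the ground with a horizontal line of sight ('S') and a
crossed pair of diagonal top-view cameras, the upper one mounted upside
down ('U') and the lower one mounted normally ('N').  The real barn
recordings are not publicly available, so this module renders a cow-like
composite of quadric primitives (ellipsoids for head, rump, back and
udder; capped cylinders for the four legs) into 640x480 integer-millimetre
depth maps with an aligned per-pixel body-part label mask.

Rendering is analytic ray casting: per pixel the nearest ray-primitive
intersection wins, which makes occlusion exactly testable against a
per-primitive oracle.  Depth is the distance along the optical axis
(z-depth), matching the Kinect depth-map convention; background is 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

from .exceptions import FormatError, InvalidParameterError

#: Body-part codes in feature-table column order: head, rump, back,
#: facing/averted foreleg, facing/averted hindleg, udder.
BODY_PARTS = ("He", "Ru", "Ba", "fFL", "aFL", "fHL", "aHL", "Ud")

#: 1-based label index per part code (0 is background).
PART_INDEX = {name: i + 1 for i, name in enumerate(BODY_PARTS)}

#: Depth working range in mm; returns outside it are treated as background.
DEFAULT_DEPTH_RANGE = (500, 4000)

_CAMERA_POSITIONS = ("U", "N", "S")


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics of the depth sensor (Kinect V1 defaults)."""

    image_width: int = 640
    image_height: int = 480
    horizontal_fov: float = 57.0  # degrees

    def __post_init__(self):
        if self.image_width <= 0 or self.image_height <= 0:
            raise InvalidParameterError("image dimensions must be positive")
        if not 0.0 < self.horizontal_fov < 180.0:
            raise InvalidParameterError("horizontal_fov must be in (0, 180)")

    @property
    def focal_length(self) -> float:
        """Focal length in pixels, derived from FOV and image width."""
        return (self.image_width / 2.0) / math.tan(
            math.radians(self.horizontal_fov) / 2.0
        )

    @property
    def principal_point(self) -> tuple[float, float]:
        """(cx, cy) in pixels; pixel centres at integer coordinates."""
        return ((self.image_width - 1) / 2.0, (self.image_height - 1) / 2.0)


@dataclass(frozen=True)
class CameraPose:
    """Extrinsics: camera-to-world rotation and camera position (metres).

    Camera axes: x right (image columns), y down (image rows), z forward
    (optical axis).  ``rotation`` maps camera coordinates to world
    coordinates; for upside-down mounting (preset 'U') the 180 degree roll
    is folded into the rotation, so rendering needs no special casing.
    """

    rotation: np.ndarray
    translation: np.ndarray
    preset: str | None = None
    flipped: bool = False

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise InvalidParameterError("rotation must be 3x3, translation 3-vector")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise InvalidParameterError("rotation must be orthonormal")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @property
    def optical_axis(self) -> np.ndarray:
        """Forward direction of the camera in world coordinates."""
        return self.rotation[:, 2].copy()


@dataclass(frozen=True)
class Primitive:
    """One labelled quadric surface patch of the cow composite.

    ``shape`` is 'ellipsoid' (params = three semi-axes, metres) or
    'capped-cylinder' (params = (radius, half_length), axis along local z).
    ``orientation`` maps local to world coordinates.
    """

    shape: str
    center: np.ndarray
    params: tuple[float, ...]
    part_label: str
    orientation: np.ndarray = field(
        default_factory=lambda: np.eye(3)
    )

    def __post_init__(self):
        if self.shape not in ("ellipsoid", "capped-cylinder"):
            raise InvalidParameterError(f"unknown primitive shape {self.shape!r}")
        if self.part_label not in BODY_PARTS:
            raise InvalidParameterError(f"unknown part label {self.part_label!r}")
        n_expected = 3 if self.shape == "ellipsoid" else 2
        if len(self.params) != n_expected or any(p <= 0 for p in self.params):
            raise InvalidParameterError("size parameters must be positive")
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        object.__setattr__(
            self, "orientation", np.asarray(self.orientation, dtype=float)
        )

    def intersect(self, origin: np.ndarray, dirs: np.ndarray) -> np.ndarray:
        """Smallest positive ray parameter per ray, inf where missed.

        Rays are ``origin + t * dirs``; ``dirs`` need not be normalised
        (with camera-frame z component 1, t is directly the z-depth).
        """
        o = self.orientation.T @ (origin - self.center)
        d = dirs @ self.orientation  # row-wise M^T d
        if self.shape == "ellipsoid":
            s = np.asarray(self.params)
            op, dp = o / s, d / s
            a = np.einsum("ij,ij->i", dp, dp)
            b = 2.0 * dp @ op
            c = op @ op - 1.0
            return _quadratic_smallest_positive(a, b, c)
        radius, hl = self.params
        a = d[:, 0] ** 2 + d[:, 1] ** 2
        b = 2.0 * (o[0] * d[:, 0] + o[1] * d[:, 1])
        c = o[0] ** 2 + o[1] ** 2 - radius**2
        t_side = _quadratic_smallest_positive(a, b, c, z0=o[2], dz=d[:, 2], zlim=hl)
        # end caps: t where local z hits +-hl inside the radius
        t_cap = np.full(len(d), np.inf)
        dz = d[:, 2]
        moving = np.abs(dz) > 1e-12
        for zc in (-hl, hl):
            t = np.where(moving, (zc - o[2]) / np.where(moving, dz, 1.0), np.inf)
            x = o[0] + t * d[:, 0]
            y = o[1] + t * d[:, 1]
            ok = (t > 1e-9) & (x**2 + y**2 <= radius**2)
            t_cap = np.where(ok & (t < t_cap), t, t_cap)
        return np.minimum(t_side, t_cap)


def _quadratic_smallest_positive(a, b, c, z0=None, dz=None, zlim=None):
    """Solve a t^2 + b t + c = 0 per ray; smallest positive valid root.

    For cylinders the side-surface roots are additionally constrained to
    |z0 + t dz| <= zlim.
    """
    a = np.broadcast_to(np.asarray(a, dtype=float), np.shape(b)).copy()
    disc = b * b - 4.0 * a * c
    hit = (disc >= 0.0) & (a > 1e-18)
    sq = np.sqrt(np.where(hit, disc, 0.0))
    out = np.full(np.shape(b), np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        for sign in (-1.0, 1.0):
            t = (-b + sign * sq) / (2.0 * a)
            ok = hit & (t > 1e-9)
            if zlim is not None:
                ok &= np.abs(z0 + t * dz) <= zlim
            out = np.where(ok & (t < out), t, out)
    return out


@dataclass(frozen=True)
class CowModel:
    """Labelled composite of quadric primitives approximating a cow."""

    primitives: tuple[Primitive, ...]
    sacrum_height: float = 1.46
    body_length: float = 2.4
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "primitives", tuple(self.primitives))

    @property
    def part_labels(self) -> set[str]:
        return {p.part_label for p in self.primitives}


@dataclass
class DepthScene:
    """A depth map (integer mm, 0 = background) plus aligned label mask."""

    depth: np.ndarray
    labels: np.ndarray
    pose: CameraPose | None = None
    noise_sigma: float = 0.0

    def __post_init__(self):
        self.depth = np.asarray(self.depth)
        self.labels = np.asarray(self.labels)
        if self.depth.shape != self.labels.shape:
            raise InvalidParameterError("depth and labels must share dimensions")

    def validate(self, depth_range=DEFAULT_DEPTH_RANGE):
        """Check the background/label consistency and range invariants."""
        fg = self.depth > 0
        if not np.array_equal(fg, self.labels > 0):
            raise InvalidParameterError("depth[p]=0 must coincide with labels[p]=0")
        if fg.any():
            vals = self.depth[fg]
            if vals.min() < depth_range[0] or vals.max() > depth_range[1]:
                raise InvalidParameterError("foreground depth outside working range")
        return self


# ---------------------------------------------------------------------------
# Cow construction
# ---------------------------------------------------------------------------

def build_cow(
    sacrum_height: float = 1.46,
    body_length: float = 2.4,
    seed: int = 0,
) -> CowModel:
    """Assemble a labelled quadric cow.

    World frame: x along the walking direction (head at +x), y across the
    passage (camera side at negative y), z up.  All vertical coordinates
    scale with ``sacrum_height`` (the recorded herd spanned 1.43-1.49 m)
    and horizontal ones with ``body_length``; the seed applies a small
    (+-2%) deterministic size jitter so different "cows" are not clones.
    """
    if sacrum_height <= 0 or body_length <= 0:
        raise InvalidParameterError("cow dimensions must be positive")
    h, L = float(sacrum_height), float(body_length)
    rng = np.random.default_rng(seed)

    def jit():
        return 1.0 + rng.uniform(-0.02, 0.02)

    specs = [
        # (shape, center, params, label)
        ("ellipsoid", (0.04 * L, 0.0, 0.795 * h),
         (0.31 * L * jit(), 0.21 * h * jit(), 0.205 * h * jit()), "Ba"),
        ("ellipsoid", (-0.33 * L, 0.0, 0.76 * h),
         (0.13 * L * jit(), 0.19 * h * jit(), 0.20 * h * jit()), "Ru"),
        ("ellipsoid", (0.45 * L, 0.0, 0.62 * h),
         (0.10 * L * jit(), 0.085 * h * jit(), 0.10 * h * jit()), "He"),
        # udder tucked fully inside the torso's plan-view outline so the
        # body occludes it from (near-)overhead viewpoints
        ("ellipsoid", (-0.158 * L, 0.0, 0.54 * h),
         (0.05 * L * jit(), 0.08 * h * jit(), 0.13 * h * jit()), "Ud"),
    ]
    prims = [
        Primitive(shape, np.array(c), params, label)
        for shape, c, params, label in specs
    ]
    # legs: capped cylinders splayed outward (wide stance) so the averted
    # pair peeks beyond the body silhouette in top views
    tilt = math.radians(25.0)
    half_len = 0.325 * h
    for x, side, label in [
        (0.26 * L, -1, "fFL"),
        (0.26 * L, +1, "aFL"),
        (-0.30 * L, -1, "fHL"),
        (-0.30 * L, +1, "aHL"),
    ]:
        ca, sa = math.cos(tilt), math.sin(tilt)
        rot_x = np.array([[1, 0, 0], [0, ca, -side * sa], [0, side * sa, ca]])
        axis = rot_x @ np.array([0.0, 0.0, 1.0])
        top = np.array([x, side * 0.17 * h, 0.65 * h])  # hip/shoulder anchor
        prims.append(
            Primitive(
                "capped-cylinder",
                top - axis * half_len,
                (0.034 * h * jit(), half_len),
                label,
                orientation=rot_x,
            )
        )
    return CowModel(tuple(prims), sacrum_height=h, body_length=L, seed=seed)


# ---------------------------------------------------------------------------
# Camera pose presets
# ---------------------------------------------------------------------------

def _look_at(position, target, roll180=False):
    position = np.asarray(position, dtype=float)
    z = np.asarray(target, dtype=float) - position
    z = z / np.linalg.norm(z)
    x = np.cross(z, np.array([0.0, 0.0, 1.0]))
    x = x / np.linalg.norm(x)
    y = np.cross(z, x)
    R = np.column_stack([x, y, z])
    if roll180:
        R = np.column_stack([-x, -y, z])
    return R, position


def preset_pose(
    position: str,
    passage_width: float = 2.0,
    top_height: float = 3.6,
    n_height: float = 1.8,
    side_standoff: float = 2.2,
) -> CameraPose:
    """Viewing geometry of the recording unit's three camera positions.

    'S' is the side-view camera: 0.6 m above the ground, horizontal line
    of sight across the passage; its standoff is chosen so a whole cow
    fits one 57-degree frame.  'N' is the lower top-view camera with a
    shallow downward-inward diagonal axis (the udder stays visible under
    the belly); 'U' is the upper top-view camera, mounted upside down,
    with a steep, near-overhead downward-inward axis from which the torso
    occludes the udder while the splayed legs remain visible.  Heights
    and standoffs beyond the documented 0.6 m are configuration (the
    original unit's exact top-view geometry is not on record).
    """
    if position not in _CAMERA_POSITIONS:
        raise InvalidParameterError(f"unknown camera position {position!r}")
    half = passage_width / 2.0
    if position == "S":
        pos = np.array([0.0, -(half + side_standoff), 0.6])
        # optical axis exactly horizontal (+y), image x along walking dir
        R = np.array([[1.0, 0.0, 0.0], [0.0, 0.0, 1.0], [0.0, -1.0, 0.0]])
        return CameraPose(R, pos, preset="S", flipped=False)
    if position == "N":
        R, pos = _look_at([0.0, -(half + 1.4), n_height], [0.0, 0.0, 1.0])
        return CameraPose(R, pos, preset="N", flipped=False)
    R, pos = _look_at([0.0, -0.3, top_height], [0.0, 0.1, 0.9], roll180=True)
    return CameraPose(R, pos, preset="U", flipped=True)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render_depth(
    cow: CowModel,
    intrinsics: CameraIntrinsics | None = None,
    pose: CameraPose | None = None,
    noise_sigma: float = 2.0,
    seed: int = 0,
    depth_range: tuple[int, int] = DEFAULT_DEPTH_RANGE,
) -> DepthScene:
    """Ray-cast the cow into an integer-mm depth map with labels.

    Per pixel the nearest ray-primitive intersection wins; depth is the
    distance along the optical axis in millimetres plus Gaussian noise of
    standard deviation ``noise_sigma`` (mm), rounded to integers.  Pixels
    with no intersection, or whose depth falls outside ``depth_range``,
    are background (depth 0, label 0).
    """
    if noise_sigma < 0:
        raise InvalidParameterError("noise_sigma must be >= 0")
    intr = intrinsics or CameraIntrinsics()
    pose = pose or preset_pose("S")
    H, W = intr.image_height, intr.image_width
    if not cow.primitives:
        z = np.zeros((H, W), dtype=np.int32)
        return DepthScene(z, z.copy().astype(np.uint8), pose, noise_sigma)

    cx, cy = intr.principal_point
    f = intr.focal_length
    cols, rows = np.meshgrid(np.arange(W), np.arange(H))
    cam_dirs = np.stack(
        [
            (cols.ravel() - cx) / f,
            (rows.ravel() - cy) / f,
            np.ones(H * W),
        ],
        axis=1,
    )
    dirs = cam_dirs @ pose.rotation.T  # world directions, z-cam component 1
    origin = pose.translation

    t_best = np.full(H * W, np.inf)
    label = np.zeros(H * W, dtype=np.uint8)
    for prim in cow.primitives:
        t = prim.intersect(origin, dirs)
        closer = t < t_best
        t_best = np.where(closer, t, t_best)
        label[closer] = PART_INDEX[prim.part_label]

    hit = np.isfinite(t_best)
    depth_mm = np.zeros(H * W)
    depth_mm[hit] = t_best[hit] * 1000.0
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        depth_mm[hit] += rng.normal(0.0, noise_sigma, size=int(hit.sum()))
    depth = np.where(hit, np.rint(depth_mm), 0.0).astype(np.int32)
    in_range = hit & (depth >= depth_range[0]) & (depth <= depth_range[1])
    depth[~in_range] = 0
    label[~in_range] = 0
    return DepthScene(
        depth.reshape(H, W), label.reshape(H, W), pose, noise_sigma
    )


# ---------------------------------------------------------------------------
# PGM round trip
# ---------------------------------------------------------------------------

def scene_to_pgm(scene: DepthScene, path) -> None:
    """Write a scene as a 16-bit depth PGM + 8-bit label PGM + JSON sidecar."""
    path = Path(path)
    if scene.depth.max(initial=0) >= 65536 or scene.depth.min(initial=0) < 0:
        raise InvalidParameterError("depth values must fit 16-bit PGM")
    Image.fromarray(scene.depth.astype(np.uint16)).save(path, format="PPM")
    Image.fromarray(scene.labels.astype(np.uint8)).save(
        _labels_path(path), format="PPM"
    )
    meta = {"noise_sigma": scene.noise_sigma}
    if scene.pose is not None:
        meta.update(
            preset=scene.pose.preset,
            flipped=scene.pose.flipped,
            rotation=scene.pose.rotation.tolist(),
            translation=scene.pose.translation.tolist(),
        )
    _meta_path(path).write_text(json.dumps(meta, indent=1))


def pgm_to_scene(path) -> DepthScene:
    """Read back a scene written by :func:`scene_to_pgm` (bit-exact)."""
    path = Path(path)
    depth = _read_pgm(path).astype(np.int32)
    labels = _read_pgm(_labels_path(path)).astype(np.uint8)
    pose, sigma = None, 0.0
    mp = _meta_path(path)
    if mp.exists():
        meta = json.loads(mp.read_text())
        sigma = meta.get("noise_sigma", 0.0)
        if "rotation" in meta:
            pose = CameraPose(
                np.array(meta["rotation"]),
                np.array(meta["translation"]),
                preset=meta.get("preset"),
                flipped=meta.get("flipped", False),
            )
    return DepthScene(depth, labels, pose, sigma)


def _labels_path(path: Path) -> Path:
    return path.with_suffix(".labels.pgm")


def _meta_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _read_pgm(path: Path) -> np.ndarray:
    try:
        with Image.open(path) as im:
            return np.asarray(im)
    except (UnidentifiedImageError, OSError, SyntaxError) as exc:
        raise FormatError(f"cannot read PGM {path}: {exc}") from exc
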