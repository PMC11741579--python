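"""Direction grids, coordinate systems and head rotations.

Conventions used throughout the package:

* Cartesian head frame: ``x`` points out of the nose, ``y`` out of the left
  ear, ``z`` up.  Directions are unit vectors.
* Lateral-polar (interaural) coordinates: the lateral angle ``theta`` in
  ``[-90, 90]`` degrees is the angle off the median plane
  (``theta = asin(y)``); the polar angle ``phi`` in ``(-180, 180]`` degrees
  runs around the interaural axis, with 0 straight ahead, +90 straight up,
  +/-180 straight behind and -90 straight below.  On the lateral poles
  (``|theta| = 90``) the polar angle is undefined and reported as 0.
* Head orientation: intrinsic yaw (about ``z``, positive toward the left),
  pitch (positive nose-up) and roll (about ``x``), in degrees.

Angles are degrees at every public interface; radians appear only inside
function bodies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

__all__ = [
    "LateralPolar",
    "HeadOrientation",
    "DirectionGrid",
    "make_direction_grid",
    "cart_to_latpolar",
    "latpolar_to_cart",
    "head_rotation",
    "rotate_into_head_frame",
    "nearest_grid_index",
]

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))
_POLE_EPS = 1.0 - 1e-12


@dataclass(frozen=True)
class LateralPolar:
    """Lateral-polar coordinate pair in degrees."""

    lateral: float
    polar: float

    def __post_init__(self) -> None:
        if not (-90.0 <= self.lateral <= 90.0):
            raise ValueError(f"lateral angle {self.lateral} outside [-90, 90]")
        if not (-180.0 < self.polar <= 180.0):
            raise ValueError(f"polar angle {self.polar} outside (-180, 180]")


@dataclass(frozen=True)
class HeadOrientation:
    """Intrinsic yaw/pitch/roll of the head relative to the world frame."""

    yaw: float = 0.0
    pitch: float = 0.0
    roll: float = 0.0

    def __post_init__(self) -> None:
        if not (-180.0 < self.yaw <= 180.0):
            raise ValueError(f"yaw {self.yaw} outside (-180, 180]")
        if not (-90.0 <= self.pitch <= 90.0):
            raise ValueError(f"pitch {self.pitch} outside [-90, 90]")
        if not (-180.0 < self.roll <= 180.0):
            raise ValueError(f"roll {self.roll} outside (-180, 180]")


def head_rotation(h: HeadOrientation) -> Rotation:
    """Rotation mapping head-frame vectors to world-frame vectors.

    Positive yaw turns the nose toward +y (left), positive pitch raises the
    nose toward +z, positive roll tips the head toward the right shoulder.
    """
    return Rotation.from_euler("ZYX", [h.yaw, -h.pitch, h.roll], degrees=True)


def _as_unit(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    n = np.linalg.norm(d)
    if n < 1e-12:
        raise ValueError("zero vector is not a direction")
    if abs(n - 1.0) > 1e-9:
        raise ValueError(f"direction must be a unit vector (norm {n})")
    return d


def cart_to_latpolar(d: np.ndarray) -> LateralPolar:
    """Convert a unit direction vector to lateral-polar coordinates."""
    d = _as_unit(d)
    y = float(np.clip(d[1], -1.0, 1.0))
    lateral = float(np.degrees(np.arcsin(y)))
    if abs(y) >= _POLE_EPS:
        # polar angle is undefined on the interaural poles
        return LateralPolar(lateral=np.sign(y) * 90.0, polar=0.0)
    polar = float(np.degrees(np.arctan2(d[2], d[0])))
    if polar <= -180.0:
        polar = 180.0
    return LateralPolar(lateral=lateral, polar=polar)


def latpolar_to_cart(lp: LateralPolar) -> np.ndarray:
    """Convert lateral-polar coordinates to a unit direction vector."""
    th = np.radians(lp.lateral)
    ph = np.radians(lp.polar)
    rho = np.cos(th)
    return np.array([rho * np.cos(ph), np.sin(th), rho * np.sin(ph)])


def rotate_into_head_frame(d: np.ndarray, h: HeadOrientation) -> np.ndarray:
    """Express a world-frame direction in the (rotated) head frame.

    A source straight ahead in the world appears at lateral -10 deg after a
    +10 deg (leftward) yaw rotation of the head.
    """
    d = _as_unit(d)
    return head_rotation(h).inv().apply(d)


class DirectionGrid:
    """Quasi-uniform set of unit directions with solid-angle weights.

    Built from a deterministic Fibonacci spiral: the same point count always
    yields the identical grid.  Each point carries an equal solid-angle share
    ``4*pi / n``.
    """

    def __init__(self, points: np.ndarray, weights: np.ndarray):
        points = np.asarray(points, dtype=float)
        weights = np.asarray(weights, dtype=float)
        if points.ndim != 2 or points.shape[1] != 3:
            raise ValueError("points must have shape (n, 3)")
        if weights.shape != (points.shape[0],):
            raise ValueError("weights must have shape (n,)")
        norms = np.linalg.norm(points, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("grid points must be unit vectors")
        if np.any(weights <= 0):
            raise ValueError("quadrature weights must be positive")
        self.points = points
        self.weights = weights
        self._tree: cKDTree | None = None

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def n(self) -> int:
        return len(self)

    @property
    def tree(self) -> cKDTree:
        if self._tree is None:
            self._tree = cKDTree(self.points)
        return self._tree

    def nearest(self, d: np.ndarray) -> int:
        return nearest_grid_index(self, d)

    def nearest_many(self, dirs: np.ndarray) -> np.ndarray:
        """Indices of the closest grid points for an (m, 3) array of units."""
        _, idx = self.tree.query(np.asarray(dirs, dtype=float), k=1)
        return np.atleast_1d(idx)

    def lateral_polar(self) -> np.ndarray:
        """(n, 2) array of lateral/polar angles in degrees."""
        out = np.empty((len(self), 2))
        for i, p in enumerate(self.points):
            lp = cart_to_latpolar(p)
            out[i] = (lp.lateral, lp.polar)
        return out

    @property
    def elevation(self) -> np.ndarray:
        """Elevation angle (deg above the horizontal plane) per point."""
        return np.degrees(np.arcsin(np.clip(self.points[:, 2], -1.0, 1.0)))

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            {
                "index": np.arange(len(self)),
                "x": self.points[:, 0],
                "y": self.points[:, 1],
                "z": self.points[:, 2],
                "weight": self.weights,
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DirectionGrid":
        df = pd.read_csv(path).sort_values("index")
        return cls(df[["x", "y", "z"]].to_numpy(), df["weight"].to_numpy())


def make_direction_grid(n: int = 2042) -> DirectionGrid:
    """Build a deterministic Fibonacci-spiral grid of ``n`` directions."""
    if n < 4:
        raise ValueError("a direction grid needs at least 4 points")
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    az = i * _GOLDEN_ANGLE
    points = np.column_stack([rho * np.cos(az), rho * np.sin(az), z])
    points /= np.linalg.norm(points, axis=1, keepdims=True)
    weights = np.full(n, 4.0 * np.pi / n)
    return DirectionGrid(points, weights)


def nearest_grid_index(grid: DirectionGrid, d: np.ndarray) -> int:
    """Index of the grid point with maximal dot product with ``d``.

    Ties break to the lowest index (``argmax`` semantics).
    """
    d = np.asarray(d, dtype=float)
    return int(np.argmax(grid.points @ d))
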