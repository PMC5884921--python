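"""Core domain types shared by every stage of the reconstruction pipeline.

Conventions used throughout the package:

* Voxel indices are 0-based.  Voxel ``i`` of an axis maps to world
  coordinate ``origin + i * spacing`` (mm).  The world frame is
  right-handed with axes ordered ``(ML, AP, DV)`` — mediolateral,
  anteroposterior, dorsoventral.
* Section images are 2D arrays indexed ``(ML, DV)``; the stack (cutting)
  axis is AP, matching coronal sectioning.
* Rigid/affine transforms are *forward point maps*: they describe where a
  physical point moves.  Images are resampled through the inverse map, so
  a bright spot at ``p`` appears at ``T(p)`` after :func:`apply_rigid_2d`.
* Displacement fields are *pull-back* (resampling) fields in mm on the
  grid of the fixed image: warping samples the input at ``x + u(x)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "Volume3D",
    "SectionSeries",
    "RigidTransform2D",
    "AffineTransform3D",
    "DisplacementField",
    "LandmarkSet",
]

_DEFAULT_AXES = ("ML", "AP", "DV")


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr


@dataclass
class Volume3D:
    """Dense 3D scalar (or 3D + channel) image with physical geometry.

    Parameters
    ----------
    values
        Array of shape ``(n0, n1, n2)`` or ``(n0, n1, n2, c)`` with
        ``c in {1, 3}``; all values finite.
    spacing
        Per-axis voxel size in mm, strictly positive.
    origin
        World position (mm) of voxel ``(0, 0, 0)``.
    axes
        Semantic axis labels; defaults to ``("ML", "AP", "DV")``.
    """

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = None  # type: ignore[assignment]
    axes: tuple = _DEFAULT_AXES

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim not in (3, 4):
            raise ValueError("Volume3D values must be 3D or 3D+channel")
        if self.values.ndim == 4 and self.values.shape[-1] not in (1, 3):
            raise ValueError("channel count must be 1 or 3")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("Volume3D values must be finite")
        self.spacing = _as_float_array(self.spacing, "spacing")
        if self.spacing.shape == ():
            self.spacing = np.repeat(self.spacing, 3)
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValueError("spacing must be 3 positive values")
        if self.origin is None:
            self.origin = np.zeros(3)
        self.origin = _as_float_array(self.origin, "origin")
        if self.origin.shape != (3,):
            raise ValueError("origin must be a 3-vector")
        self.axes = tuple(self.axes)

    @property
    def shape(self) -> tuple:
        """Spatial grid shape (channels excluded)."""
        return self.values.shape[:3]

    @property
    def n_channels(self) -> int:
        return 1 if self.values.ndim == 3 else self.values.shape[-1]

    def extent_mm(self) -> np.ndarray:
        """Physical extent per axis (voxel-edge convention: n * spacing)."""
        return np.array(self.shape) * self.spacing

    def index_to_world(self, idx) -> np.ndarray:
        return self.origin + np.asarray(idx, dtype=float) * self.spacing

    def world_to_index(self, world) -> np.ndarray:
        return (np.asarray(world, dtype=float) - self.origin) / self.spacing

    def with_values(self, values: np.ndarray) -> "Volume3D":
        return Volume3D(values, self.spacing.copy(), self.origin.copy(), self.axes)


@dataclass
class SectionSeries:
    """Ordered series of 2D section images cut from one specimen.

    ``sections`` all share shape, pixel size and channel count.
    ``thickness`` is the physical thickness of one cut (mm); when the
    specimen is split into ``interleave`` alternating staining series the
    within-series spacing is ``thickness * interleave``.  ``parity`` says
    which interleave slot this series occupies, so section ``i`` of the
    series corresponds to physical cut ``interleave * i + parity``.
    """

    sections: list
    pixel_size: float
    thickness: float = 0.040
    interleave: int = 1
    parity: int = 0
    qc_flags: list = None  # type: ignore[assignment]

    def __post_init__(self):
        self.sections = [np.asarray(s, dtype=float) for s in self.sections]
        if len(self.sections) < 2:
            raise ValueError("SectionSeries needs at least 2 sections")
        shape0 = self.sections[0].shape
        for s in self.sections:
            if s.shape != shape0:
                raise ValueError("all sections must share shape and channels")
        if self.pixel_size <= 0 or self.thickness <= 0:
            raise ValueError("pixel_size and thickness must be positive")
        if not (0 <= self.parity < self.interleave):
            raise ValueError("parity must satisfy 0 <= parity < interleave")
        if self.qc_flags is None:
            self.qc_flags = [False] * len(self.sections)
        if len(self.qc_flags) != len(self.sections):
            raise ValueError("one qc flag per section required")

    def __len__(self) -> int:
        return len(self.sections)

    @property
    def section_shape(self) -> tuple:
        return self.sections[0].shape

    @property
    def z_spacing(self) -> float:
        """Within-series stack spacing in mm."""
        return self.thickness * self.interleave

    def physical_index(self, i: int) -> int:
        """Physical cut number of series section ``i``."""
        return self.interleave * i + self.parity

    def copy(self) -> "SectionSeries":
        return SectionSeries(
            [s.copy() for s in self.sections],
            self.pixel_size,
            self.thickness,
            self.interleave,
            self.parity,
            list(self.qc_flags),
        )


@dataclass
class RigidTransform2D:
    """In-plane rigid motion ``y = R(theta) (x - center) + center + t``.

    ``theta`` is the rotation angle in radians (counter-clockwise in the
    ``(ML, DV)`` plane), ``t`` the translation in mm and ``center`` the
    rotation center in mm.  Acts as a forward point map.
    """

    theta: float = 0.0
    t: np.ndarray = None  # type: ignore[assignment]
    center: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        if not np.isfinite(self.theta):
            raise ValueError("theta must be finite")
        if abs(self.theta) >= np.pi:
            raise ValueError("|theta| must be < pi")
        self.t = np.zeros(2) if self.t is None else _as_float_array(self.t, "t")
        self.center = (
            np.zeros(2) if self.center is None else _as_float_array(self.center, "center")
        )
        if self.t.shape != (2,) or self.center.shape != (2,):
            raise ValueError("t and center must be 2-vectors")

    @property
    def rotation(self) -> np.ndarray:
        c, s = np.cos(self.theta), np.sin(self.theta)
        return np.array([[c, -s], [s, c]])

    def matrix(self) -> np.ndarray:
        """3x3 homogeneous forward matrix."""
        R = self.rotation
        b = self.center + self.t - R @ self.center
        M = np.eye(3)
        M[:2, :2] = R
        M[:2, 2] = b
        return M

    def apply_points(self, pts) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return (self.rotation @ (pts - self.center).T).T + self.center + self.t

    def inverse(self) -> "RigidTransform2D":
        R = self.rotation
        # inverse about the same center: y = R^T (x - c) + c + t'
        t_inv = -(R.T @ self.t)
        return RigidTransform2D(-self.theta, t_inv, self.center.copy())

    def parameters(self) -> np.ndarray:
        """(theta, tx, ty) — the scalars smoothed by the merge step."""
        return np.array([self.theta, self.t[0], self.t[1]])

    @staticmethod
    def identity(center=None) -> "RigidTransform2D":
        return RigidTransform2D(0.0, np.zeros(2), center)


@dataclass
class AffineTransform3D:
    """Forward affine point map ``y = linear @ x + translation`` (mm)."""

    linear: np.ndarray = None  # type: ignore[assignment]
    translation: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.linear = (
            np.eye(3) if self.linear is None else _as_float_array(self.linear, "linear")
        )
        self.translation = (
            np.zeros(3)
            if self.translation is None
            else _as_float_array(self.translation, "translation")
        )
        if self.linear.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("linear must be 3x3 and translation a 3-vector")
        if abs(np.linalg.det(self.linear)) <= 1e-8:
            raise ValueError("linear part must be invertible")

    def apply_points(self, pts) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return (self.linear @ pts.T).T + self.translation

    def inverse(self) -> "AffineTransform3D":
        Ainv = np.linalg.inv(self.linear)
        return AffineTransform3D(Ainv, -Ainv @ self.translation)

    def compose(self, other: "AffineTransform3D") -> "AffineTransform3D":
        """Return self ∘ other (apply ``other`` first)."""
        return AffineTransform3D(
            self.linear @ other.linear,
            self.linear @ other.translation + self.translation,
        )

    @staticmethod
    def identity() -> "AffineTransform3D":
        return AffineTransform3D()


@dataclass
class DisplacementField:
    """Per-voxel displacement vectors (mm) on a named reference grid.

    ``vectors`` has shape ``grid_shape + (ndim,)``; the field is a
    pull-back map: warping an image samples it at ``x + u(x)``.
    """

    vectors: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        ndim = self.vectors.ndim - 1
        if ndim not in (2, 3) or self.vectors.shape[-1] != ndim:
            raise ValueError("vectors must be (grid..., ndim) with ndim 2 or 3")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("displacement vectors must be finite")
        self.spacing = _as_float_array(self.spacing, "spacing")
        if self.spacing.shape == ():
            self.spacing = np.repeat(self.spacing, ndim)
        if self.spacing.shape != (ndim,) or np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive, one value per grid axis")
        if self.origin is None:
            self.origin = np.zeros(ndim)
        self.origin = _as_float_array(self.origin, "origin")
        if self.origin.shape != (ndim,):
            raise ValueError("origin must match grid dimensionality")

    @property
    def ndim(self) -> int:
        return self.vectors.shape[-1]

    @property
    def grid_shape(self) -> tuple:
        return self.vectors.shape[:-1]

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=-1)

    def same_grid(self, other: "DisplacementField", tol: float = 1e-9) -> bool:
        return (
            self.grid_shape == other.grid_shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    @staticmethod
    def zero(grid_shape, spacing, origin=None) -> "DisplacementField":
        grid_shape = tuple(grid_shape)
        return DisplacementField(
            np.zeros(grid_shape + (len(grid_shape),)), spacing, origin
        )


@dataclass
class LandmarkSet:
    """Named 3D points in world mm, the currency of accuracy evaluation."""

    names: list
    coords: np.ndarray

    def __post_init__(self):
        self.names = [str(n) for n in self.names]
        if len(set(self.names)) != len(self.names):
            raise ValueError("landmark names must be unique")
        self.coords = _as_float_array(self.coords, "coords")
        self.coords = np.atleast_2d(self.coords)
        if self.coords.shape != (len(self.names), 3):
            raise ValueError("coords must be (n_landmarks, 3)")

    def __len__(self) -> int:
        return len(self.names)

    def as_dict(self) -> dict:
        return {n: c.copy() for n, c in zip(self.names, self.coords)}

    def copy(self) -> "LandmarkSet":
        return LandmarkSet(list(self.names), self.coords.copy())

    @staticmethod
    def from_points(coords, prefix: str = "lm") -> "LandmarkSet":
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        names = [f"{prefix}{i:04d}" for i in range(len(coords))]
        return LandmarkSet(names, coords)
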