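"""Spatial transform algebra, warping and resampling.

All operations follow the package conventions (see :mod:`serialrecon.types`):
transforms are forward point maps, displacement fields are pull-back
resampling fields in mm, images are resampled through the inverse map so
features move *with* the transform.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .types import (
    AffineTransform3D,
    DisplacementField,
    LandmarkSet,
    RigidTransform2D,
    Volume3D,
)

__all__ = [
    "image_center_mm",
    "apply_rigid_2d",
    "compose_rigid_2d",
    "invert_rigid_2d",
    "warp_with_field",
    "compose_fields",
    "invert_displacement_field",
    "jacobian_determinant",
    "resample_volume",
    "transform_landmarks",
]

_ORDER = {"linear": 1, "nearest": 0}


def image_center_mm(shape, pixel_size: float) -> np.ndarray:
    """Physical center of a pixel grid — the default rotation center."""
    return (np.asarray(shape, dtype=float) - 1.0) / 2.0 * pixel_size


def _check_interp(interpolation: str) -> int:
    if interpolation not in _ORDER:
        raise ValueError(f"interpolation must be one of {sorted(_ORDER)}")
    return _ORDER[interpolation]


def apply_rigid_2d(
    image: np.ndarray,
    transform: RigidTransform2D,
    pixel_size: float,
    interpolation: str = "linear",
    background: float = 0.0,
) -> np.ndarray:
    """Resample ``image`` under the forward rigid map ``transform``.

    The output lives on the input grid; a feature at physical point ``p``
    moves to ``transform(p)``.  Out-of-domain samples are filled with
    ``background``.
    """
    order = _check_interp(interpolation)
    image = np.asarray(image, dtype=float)
    inv = transform.inverse()
    R = inv.rotation
    b = inv.center + inv.t - R @ inv.center  # y = R x + b, in mm
    # pixel-space map: in_px = R @ out_px + b / pixel_size
    matrix = R
    offset = b / pixel_size
    if image.ndim == 2:
        return ndimage.affine_transform(
            image, matrix, offset=offset, order=order, mode="constant", cval=background
        )
    if image.ndim == 3:  # trailing channel axis
        out = np.empty_like(image)
        for c in range(image.shape[-1]):
            out[..., c] = ndimage.affine_transform(
                image[..., c], matrix, offset=offset, order=order,
                mode="constant", cval=background,
            )
        return out
    raise ValueError("image must be 2D or 2D+channel")


def compose_rigid_2d(A: RigidTransform2D, B: RigidTransform2D) -> RigidTransform2D:
    """Return ``A ∘ B``: applying the result equals applying B, then A.

    Both inputs must share the same center convention; the result is
    expressed about ``A.center``.
    """
    M = A.matrix() @ B.matrix()
    theta = np.arctan2(M[1, 0], M[0, 0])
    c = A.center
    R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    t = M[:2, 2] - c + R @ c
    return RigidTransform2D(theta, t, c.copy())


def invert_rigid_2d(T: RigidTransform2D) -> RigidTransform2D:
    return T.inverse()


def _sample_field_mm(field: DisplacementField, points_mm: np.ndarray) -> np.ndarray:
    """Linearly interpolate the field (mm vectors) at world points."""
    idx = (points_mm - field.origin) / field.spacing
    coords = [idx[:, a] for a in range(field.ndim)]
    out = np.empty_like(points_mm)
    for a in range(field.ndim):
        out[:, a] = ndimage.map_coordinates(
            field.vectors[..., a], coords, order=1, mode="nearest"
        )
    return out


def warp_with_field(
    data,
    field: DisplacementField,
    interpolation: str = "linear",
    background: float = 0.0,
):
    """Warp an image/volume by a pull-back field: ``out(x) = in(x + u(x))``.

    ``data`` may be a raw 2D array (grid geometry taken from the field) or
    a :class:`Volume3D`; a Volume3D input returns a Volume3D on the same
    grid.  The field grid must match the data grid.
    """
    order = _check_interp(interpolation)
    if isinstance(data, Volume3D):
        if data.shape != field.grid_shape or not np.allclose(
            data.spacing[: field.ndim], field.spacing
        ):
            raise ValueError("field grid geometry must match the volume grid")
        warped = _warp_array(data.values, field, order, background)
        return data.with_values(warped)
    arr = np.asarray(data, dtype=float)
    if arr.shape[: field.ndim] != field.grid_shape:
        raise ValueError("field grid geometry must match the image grid")
    return _warp_array(arr, field, order, background)


def _warp_array(arr: np.ndarray, field: DisplacementField, order: int, cval: float):
    grids = np.meshgrid(
        *[np.arange(n, dtype=float) for n in field.grid_shape], indexing="ij"
    )
    coords = [
        grids[a] + field.vectors[..., a] / field.spacing[a] for a in range(field.ndim)
    ]
    if arr.ndim == field.ndim:
        return ndimage.map_coordinates(arr, coords, order=order, mode="constant", cval=cval)
    out = np.empty_like(arr, dtype=float)
    for c in range(arr.shape[-1]):
        out[..., c] = ndimage.map_coordinates(
            arr[..., c], coords, order=order, mode="constant", cval=cval
        )
    return out


def compose_fields(outer: DisplacementField, inner: DisplacementField) -> DisplacementField:
    """Compose two pull-back fields: warp by ``inner`` after ``outer``.

    ``warp(I, result) == warp(warp(I, inner), outer)`` up to interpolation:
    ``result(x) = outer(x) + inner(x + outer(x))``.
    """
    if not outer.same_grid(inner):
        raise ValueError("fields must share a grid to compose")
    grids = np.meshgrid(
        *[np.arange(n, dtype=float) for n in outer.grid_shape], indexing="ij"
    )
    pts = np.stack(
        [grids[a] * outer.spacing[a] + outer.origin[a] for a in range(outer.ndim)],
        axis=-1,
    )
    moved = (pts + outer.vectors).reshape(-1, outer.ndim)
    inner_at = _sample_field_mm(inner, moved).reshape(outer.vectors.shape)
    return DisplacementField(outer.vectors + inner_at, outer.spacing.copy(), outer.origin.copy())


def invert_displacement_field(
    field: DisplacementField, n_iter: int = 30, tol_mm: float = 1e-4
) -> DisplacementField:
    """Fixed-point inverse of a pull-back field.

    Solves ``v(x) = -u(x + v(x))`` so that warping by ``u`` then ``v``
    is the identity (up to interpolation).  Converges for smooth fields
    with displacement gradients below 1.
    """
    grids = np.meshgrid(
        *[np.arange(n, dtype=float) for n in field.grid_shape], indexing="ij"
    )
    pts = np.stack(
        [grids[a] * field.spacing[a] + field.origin[a] for a in range(field.ndim)],
        axis=-1,
    ).reshape(-1, field.ndim)
    v = np.zeros_like(pts)
    for _ in range(n_iter):
        v_new = -_sample_field_mm(field, pts + v)
        delta = np.max(np.abs(v_new - v))
        v = v_new
        if delta < tol_mm:
            break
    return DisplacementField(
        v.reshape(field.vectors.shape), field.spacing.copy(), field.origin.copy()
    )


def jacobian_determinant(field: DisplacementField) -> np.ndarray:
    """Determinant of ``d(x + u(x))/dx`` per voxel (negative = folding)."""
    ndim = field.ndim
    grads = np.empty(field.grid_shape + (ndim, ndim))
    for a in range(ndim):
        for b in range(ndim):
            grads[..., a, b] = np.gradient(
                field.vectors[..., a], field.spacing[b], axis=b
            )
            if a == b:
                grads[..., a, b] += 1.0
    return np.linalg.det(grads)


def resample_volume(volume: Volume3D, new_spacing) -> Volume3D:
    """Resample to a new voxel size, preserving world extent and origin.

    The new grid shape is ``round(extent / new_spacing)`` per axis (within
    one voxel of the exact extent).  Linear interpolation; the intensity
    range is not expanded.
    """
    new_spacing = np.asarray(new_spacing, dtype=float)
    if new_spacing.shape == ():
        new_spacing = np.repeat(new_spacing, 3)
    if new_spacing.shape != (3,) or np.any(new_spacing <= 0):
        raise ValueError("new_spacing must be positive, one value per axis")
    if np.allclose(new_spacing, volume.spacing):
        return Volume3D(volume.values.copy(), volume.spacing.copy(), volume.origin.copy(), volume.axes)
    extent = volume.extent_mm()
    new_shape = np.maximum(1, np.round(extent / new_spacing).astype(int))
    grids = np.meshgrid(
        *[np.arange(n, dtype=float) for n in new_shape], indexing="ij"
    )
    coords = [grids[a] * (new_spacing[a] / volume.spacing[a]) for a in range(3)]
    if volume.values.ndim == 3:
        vals = ndimage.map_coordinates(volume.values, coords, order=1, mode="nearest")
    else:
        vals = np.stack(
            [
                ndimage.map_coordinates(
                    volume.values[..., c], coords, order=1, mode="nearest"
                )
                for c in range(volume.values.shape[-1])
            ],
            axis=-1,
        )
    return Volume3D(vals, new_spacing, volume.origin.copy(), volume.axes)


def transform_landmarks(landmarks: LandmarkSet, mapping) -> LandmarkSet:
    """Move landmarks forward through an affine or displacement field.

    For an :class:`AffineTransform3D` the forward map is applied directly.
    For a :class:`DisplacementField` (a pull-back resampling field) the
    forward point motion is its inverse, found per landmark by fixed-point
    iteration — so landmarks move exactly where :func:`warp_with_field`
    moves image features.  Landmarks falling outside the field grid are
    moved using edge-clamped field values and flagged via the returned
    set's name suffix "!offgrid" — they are never silently dropped.
    """
    if isinstance(mapping, AffineTransform3D):
        return LandmarkSet(list(landmarks.names), mapping.apply_points(landmarks.coords))
    if isinstance(mapping, DisplacementField):
        field = mapping
        pts = landmarks.coords[:, : field.ndim].copy()
        v = np.zeros_like(pts)
        for _ in range(30):
            v_new = -_sample_field_mm(field, pts + v)
            if np.max(np.abs(v_new - v)) < 1e-6:
                v = v_new
                break
            v = v_new
        moved = landmarks.coords.copy()
        moved[:, : field.ndim] = pts + v
        lo = field.origin
        hi = field.origin + (np.array(field.grid_shape) - 1) * field.spacing
        offgrid = np.any((pts < lo) | (pts > hi), axis=1)
        names = [
            n + "!offgrid" if bad else n
            for n, bad in zip(landmarks.names, offgrid)
        ]
        return LandmarkSet(names, moved)
    raise TypeError("mapping must be AffineTransform3D or DisplacementField")
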