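"""3D-to-3D coregistration of reconstructed volumes to a reference.

Two stages, as in blockface-referenced atlas building: an affine (or
rigid) registration of binary brain masks under a summed-squared-
difference criterion, then a multi-term greedy deformable registration
driven by up to three weighted similarity forces — windowed cross-
correlation on intensities, SSD on masks, and SSD on per-label signed
distance maps (an expert-guidance term attracting labeled regions to
their counterparts).

Conventions: affine transforms are forward point maps (moving points to
fixed space); the deformable output is a pull-back displacement field on
the fixed grid, applied after the affine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .transforms import _sample_field_mm, invert_displacement_field, warp_with_field
from .types import AffineTransform3D, DisplacementField, Volume3D

__all__ = [
    "affine_register_masks",
    "resample_volume_through_affine",
    "resample_mask_through_affine",
    "MultichannelParams",
    "deformable_register_multichannel",
    "CompositeMapping",
    "resolve_full_mapping",
]


def _euler_to_matrix(rx, ry, rz) -> np.ndarray:
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def _params_to_affine(x, dof: str, center: np.ndarray) -> AffineTransform3D:
    """Rigid: (rx, ry, rz, tx, ty, tz); affine adds scales and shears."""
    R = _euler_to_matrix(x[0], x[1], x[2])
    t = np.asarray(x[3:6], dtype=float)
    if dof == "affine":
        S = np.diag(np.exp(x[6:9]))
        H = np.eye(3)
        H[0, 1], H[0, 2], H[1, 2] = x[9], x[10], x[11]
        L = R @ S @ H
    else:
        L = R
    # rotation/scale about the mask centroid
    return AffineTransform3D(L, center - L @ center + t)


def _resample_through(moving: Volume3D, T: AffineTransform3D, fixed: Volume3D, order: int):
    """Sample moving at T^-1(x) on the fixed grid (forward map T)."""
    inv = T.inverse()
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in fixed.shape], indexing="ij")
    pts = np.stack(
        [grids[a] * fixed.spacing[a] + fixed.origin[a] for a in range(3)], axis=-1
    ).reshape(-1, 3)
    src = inv.apply_points(pts)
    idx = (src - moving.origin) / moving.spacing
    vals = ndimage.map_coordinates(
        moving.values, [idx[:, a].reshape(fixed.shape) for a in range(3)],
        order=order, mode="constant", cval=0.0,
    )
    return Volume3D(vals, fixed.spacing.copy(), fixed.origin.copy(), fixed.axes)


def resample_volume_through_affine(
    moving: Volume3D, T: AffineTransform3D, fixed: Volume3D
) -> Volume3D:
    return _resample_through(moving, T, fixed, order=1)


def resample_mask_through_affine(
    moving: Volume3D, T: AffineTransform3D, fixed: Volume3D
) -> Volume3D:
    return _resample_through(moving, T, fixed, order=0)


def _mask_centroid_mm(mask: Volume3D) -> np.ndarray:
    idx = np.argwhere(mask.values > 0.5)
    return mask.origin + idx.mean(axis=0) * mask.spacing


def affine_register_masks(
    moving_mask: Volume3D,
    fixed_mask: Volume3D,
    dof: str = "affine",
    smooth_vox: float = 1.5,
) -> AffineTransform3D:
    """Mask-to-mask registration minimizing the summed squared distance.

    Both masks are lightly Gaussian-smoothed so the SSD has usable
    gradients, the moving mask is initialized by centroid alignment, and
    a derivative-free (Powell) search over rigid (6) or affine (12)
    parameters refines the fit.
    """
    if dof not in ("rigid", "affine"):
        raise ValueError("dof must be 'rigid' or 'affine'")
    if not np.any(moving_mask.values > 0.5) or not np.any(fixed_mask.values > 0.5):
        raise ValueError("masks must be nonempty")
    fix_sm = ndimage.gaussian_filter((fixed_mask.values > 0.5).astype(float), smooth_vox)
    mov_sm = ndimage.gaussian_filter((moving_mask.values > 0.5).astype(float), smooth_vox)
    c_mov = _mask_centroid_mm(moving_mask)
    c_fix = _mask_centroid_mm(fixed_mask)

    n_par = 6 if dof == "rigid" else 12
    x0 = np.zeros(n_par)
    x0[3:6] = c_fix - c_mov
    scale = np.concatenate([
        np.full(3, 0.05),                    # rad
        np.full(3, 0.5 * fixed_mask.spacing.mean() * 4),  # mm
        np.full(n_par - 6, 0.02),            # log-scale / shear
    ])[:n_par]

    # coarse-to-fine: most of the search happens on a 2x-downsampled
    # grid, with a short full-resolution refinement
    levels = []
    for zoom, maxiter in ((0.5, 25), (1.0, 5)):
        if zoom == 1.0:
            fv, sp_l, or_l = fix_sm, fixed_mask.spacing, fixed_mask.origin
        else:
            fv = ndimage.zoom(fix_sm, zoom, order=1)
            sp_l = fixed_mask.spacing / zoom
            or_l = fixed_mask.origin
        grids = np.meshgrid(*[np.arange(n, dtype=float) for n in fv.shape], indexing="ij")
        pts = np.stack(
            [grids[a] * sp_l[a] + or_l[a] for a in range(3)], axis=-1
        ).reshape(-1, 3)
        levels.append((fv, pts, maxiter))

    m_origin, m_spacing = moving_mask.origin, moving_mask.spacing

    x = x0
    for fv, pts, maxiter in levels:
        def cost(u, _fv=fv, _pts=pts, _x=x):
            T = _params_to_affine(_x + u * scale, dof, c_mov)
            inv = T.inverse()
            src = _pts @ inv.linear.T + inv.translation
            idx = (src - m_origin) / m_spacing
            warped = ndimage.map_coordinates(
                mov_sm, [idx[:, a].reshape(_fv.shape) for a in range(3)],
                order=1, mode="constant", cval=0.0,
            )
            return float(np.mean((warped - _fv) ** 2))

        res = optimize.minimize(
            cost, np.zeros(n_par), method="Powell",
            options={"xtol": 1e-4, "ftol": 1e-7, "maxiter": maxiter},
        )
        x = x + res.x * scale
    return _params_to_affine(x, dof, c_mov)


@dataclass
class MultichannelParams:
    """Deformable coregistration parameters.

    ``cc_radius`` (voxels) is the window of the intensity CC force;
    ``field_reg_mm`` ramps the field-smoothing kernel radius linearly
    from first to last registration step; ``steps`` outer steps each run
    ``inner_iterations`` greedy updates with ``gradient_step`` (voxels)
    as the per-update cap.
    """

    cc_radius: int = 5
    field_reg_mm: tuple = (0.1, 0.05)
    steps: int = 10
    gradient_step: float = 0.4
    sigma_gradient_vox: float = 3.0
    inner_iterations: int = 4


def _local_normalize_3d(img: np.ndarray, radius: int) -> np.ndarray:
    size = 2 * int(radius) + 1
    mean = ndimage.uniform_filter(img, size)
    var = ndimage.uniform_filter(img**2, size) - mean**2
    floor = (0.05 * img.std()) ** 2 + 1e-12
    return (img - mean) / np.sqrt(np.maximum(var, floor))


def _signed_distance_maps(labels: np.ndarray, spacing, clip_mm: float = 0.5):
    """Signed distance map (mm, negative inside) per nonzero label."""
    out = {}
    for lab in np.unique(labels):
        if lab == 0:
            continue
        inside = labels == lab
        if not inside.any():
            continue
        d_out = ndimage.distance_transform_edt(~inside, sampling=spacing)
        d_in = ndimage.distance_transform_edt(inside, sampling=spacing)
        out[lab] = np.clip(d_out - d_in, -clip_mm, clip_mm)
    return out


def _demons_force(fixed_ch: np.ndarray, warped_ch: np.ndarray) -> np.ndarray:
    grads = np.gradient(warped_ch)
    gmag2 = sum(g**2 for g in grads)
    diff = fixed_ch - warped_ch
    denom = gmag2 + np.mean(diff**2) + 1e-8
    return np.stack([diff * g / denom for g in grads], axis=-1)


def deformable_register_multichannel(
    fixed: dict,
    moving: dict,
    weights: dict = None,
    params: MultichannelParams = None,
) -> DisplacementField:
    """Multi-term greedy deformable registration (3D).

    ``fixed`` and ``moving`` map channel names (any of ``intensity``,
    ``mask``, ``labels``) to :class:`Volume3D` on a common grid per
    side.  Label volumes must share a label dictionary; they contribute
    through SSD forces on per-label signed distance maps.  Returns a
    pull-back field on the fixed grid.
    """
    params = params or MultichannelParams()
    weights = {"intensity": 1.0, "mask": 1.0, "labels": 1.0, **(weights or {})}
    if not fixed:
        raise ValueError("at least one channel required")
    ref = next(iter(fixed.values()))
    shape, spacing = ref.shape, ref.spacing
    for side in (fixed, moving):
        for v in side.values():
            if v.shape != shape:
                raise ValueError("all channels must share one grid")

    terms = []  # (kind, weight, fixed_feature, moving_channel)
    if "intensity" in fixed and "intensity" in moving and weights["intensity"] > 0:
        terms.append((
            "cc", weights["intensity"],
            _local_normalize_3d(fixed["intensity"].values, params.cc_radius),
            moving["intensity"].values,
        ))
    if "mask" in fixed and "mask" in moving and weights["mask"] > 0:
        terms.append((
            "mask", weights["mask"],
            ndimage.gaussian_filter((fixed["mask"].values > 0.5).astype(float), 1.0),
            (moving["mask"].values > 0.5).astype(float),
        ))
    if "labels" in fixed and "labels" in moving and weights["labels"] > 0:
        f_labs = set(np.unique(fixed["labels"].values)) - {0.0}
        m_labs = set(np.unique(moving["labels"].values)) - {0.0}
        if f_labs != m_labs:
            raise ValueError("label dictionaries must match")
        f_sdm = _signed_distance_maps(fixed["labels"].values, spacing)
        m_sdm = _signed_distance_maps(moving["labels"].values, spacing)
        for lab in sorted(f_labs):
            terms.append(("sdm", weights["labels"] / len(f_labs), f_sdm[lab], m_sdm[lab]))
    if not terms:
        raise ValueError("no overlapping channels with positive weight")

    def _features(field):
        feats = []
        for kind, w, fix_feat, mov_ch in terms:
            warped = warp_with_field(mov_ch, field)
            if kind == "cc":
                feats.append((w, fix_feat, _local_normalize_3d(warped, params.cc_radius)))
            elif kind == "mask":
                feats.append((w, fix_feat, ndimage.gaussian_filter(warped, 1.0)))
            else:
                feats.append((w, fix_feat, warped))
        return feats

    def _metric(feats):
        return float(sum(w * np.mean((f - m) ** 2) for w, f, m in feats))

    field = DisplacementField.zero(shape, spacing)
    best_field = field
    best_metric = _metric(_features(field))
    worse_streak = 0
    radii = np.linspace(params.field_reg_mm[0], params.field_reg_mm[1], params.steps)
    for step in range(params.steps):
        sigma_field_vox = radii[step] / spacing  # mm -> voxels per axis
        for _ in range(params.inner_iterations):
            feats = _features(field)
            force = np.zeros(shape + (3,))
            for (kind, w, fix_feat, _mc), (_w, _f, warped_feat) in zip(terms, feats):
                force += w * _demons_force(fix_feat, warped_feat)
            if params.sigma_gradient_vox > 0:
                for a in range(3):
                    force[..., a] = ndimage.gaussian_filter(
                        force[..., a], params.sigma_gradient_vox
                    )
            mag = np.sqrt((force**2).sum(-1))
            peak = mag.max()
            if peak < 1e-12:
                break
            delta = force * (params.gradient_step / peak)
            delta_mm = delta * spacing  # voxel -> mm per axis
            field = DisplacementField(
                delta_mm + _compose_sample(field, delta_mm), spacing
            )
            vec = np.stack(
                [
                    ndimage.gaussian_filter(field.vectors[..., a], sigma_field_vox)
                    for a in range(3)
                ],
                axis=-1,
            )
            field = DisplacementField(vec, spacing)
            metric = _metric(_features(field))
            if metric < best_metric - 1e-12:
                best_metric = metric
                best_field = field
                worse_streak = 0
            else:
                worse_streak += 1
                if worse_streak >= 5:
                    return best_field
    return best_field


def _compose_sample(field: DisplacementField, delta_mm: np.ndarray) -> np.ndarray:
    """Sample ``field`` at x + delta(x) (helper for field composition)."""
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in field.grid_shape], indexing="ij")
    pts = np.stack(
        [grids[a] * field.spacing[a] + field.origin[a] for a in range(field.ndim)],
        axis=-1,
    )
    moved = (pts + delta_mm).reshape(-1, field.ndim)
    return _sample_field_mm(field, moved).reshape(field.vectors.shape)


@dataclass
class CompositeMapping:
    """Full chain from original 2D sections to reference world space.

    Components: per-section rigid transforms, per-section reconstruction
    fields (pull-back, on the rigid-space grid), the series geometry,
    the 3D affine into the reference, and the 3D coregistration field
    (pull-back, on the reference grid).  Any component may be identity /
    zero, but all must be present.
    """

    rigid: object  # TransformSeries
    recon_fields: list
    pixel_size: float
    z_positions: np.ndarray  # world AP coordinate per section, mm
    affine: AffineTransform3D
    coreg_field: DisplacementField

    def map_section_points(self, section_index: int, pts2d) -> np.ndarray:
        """Map (ML, DV) points of original section ``i`` to reference world mm."""
        pts2d = np.atleast_2d(np.asarray(pts2d, dtype=float))
        T = self.rigid.transforms[section_index]
        p = T.apply_points(pts2d)
        f = self.recon_fields[section_index]
        if f is not None and np.any(f.vectors):
            p = _invert_points_2d(f, p)
        pts3 = np.stack(
            [p[:, 0], np.full(len(p), self.z_positions[section_index]), p[:, 1]],
            axis=1,
        )
        pts3 = self.affine.apply_points(pts3)
        if self.coreg_field is not None and np.any(self.coreg_field.vectors):
            if not hasattr(self, "_coreg_inverse"):
                self._coreg_inverse = invert_displacement_field(self.coreg_field)
            pts3 = pts3 + _sample_field_mm(self._coreg_inverse, pts3)
        return pts3


def _invert_points_2d(field: DisplacementField, pts: np.ndarray) -> np.ndarray:
    """Forward point motion of a 2D pull-back field (fixed-point solve)."""
    v = np.zeros_like(pts)
    for _ in range(30):
        v_new = -_sample_field_mm(field, pts + v)
        if np.max(np.abs(v_new - v)) < 1e-6:
            v = v_new
            break
        v = v_new
    return pts + v


def resolve_full_mapping(
    rigid,
    recon_fields,
    pixel_size: float,
    z_positions,
    affine: AffineTransform3D,
    coreg_field: DisplacementField,
) -> CompositeMapping:
    """Assemble and validate the section-to-reference composite mapping."""
    if rigid is None or affine is None:
        raise ValueError("rigid series and affine are required components")
    n = len(rigid.transforms)
    if recon_fields is None or len(recon_fields) != n:
        raise ValueError("one reconstruction field (or None) per section required")
    z_positions = np.asarray(z_positions, dtype=float)
    if z_positions.shape != (n,):
        raise ValueError("one stack position per section required")
    return CompositeMapping(rigid, list(recon_fields), pixel_size, z_positions, affine, coreg_field)
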