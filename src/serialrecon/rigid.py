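"""Rigid 3D reconstruction of a section stack.

The reconstruction combines two series of per-section rigid transforms:

* *coarse* — each stained section registered to its blockface
  counterpart.  The blockface stack (itself realigned by propagation
  from a reference section) is spatially consistent with the intact
  specimen, so these transforms are anatomy-true but noisy section to
  section.
* *fine* — each section registered sequentially to its already-aligned
  inner neighbor, starting from a central section.  These transforms
  make the stack smooth but, applied alone, straighten genuinely oblique
  anatomy (the z-shift / banana effect).

The merge keeps the low-frequency (anatomy) part of the coarse series
and adds only the high-frequency (section jitter) part of the fine
series, obtained by subtracting a Gaussian-smoothed copy (sigma in
sections) of each fine parameter profile along the stack.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize
from skimage.registration import phase_cross_correlation

from .transforms import apply_rigid_2d, compose_rigid_2d, image_center_mm
from .types import RigidTransform2D, SectionSeries, Volume3D

__all__ = [
    "TransformSeries",
    "register_rigid_2d",
    "align_blockface_stack",
    "coarse_align_to_blockface",
    "fine_sequential_align",
    "merge_coarse_fine",
    "smooth_transform_series",
    "coarse_to_fine_transforms",
    "apply_transform_series",
    "reconstruct_rigid_volume",
]

logger = logging.getLogger(__name__)


@dataclass
class TransformSeries:
    """Ordered per-section rigid transforms with a reference section."""

    transforms: list
    reference_index: int = 0

    def __post_init__(self):
        if not self.transforms:
            raise ValueError("empty transform series")
        if not (0 <= self.reference_index < len(self.transforms)):
            raise ValueError("reference index out of range")

    def __len__(self) -> int:
        return len(self.transforms)

    def __getitem__(self, i: int) -> RigidTransform2D:
        return self.transforms[i]

    def parameters(self) -> np.ndarray:
        """(n, 3) array of (theta, tx, ty) per section."""
        return np.stack([T.parameters() for T in self.transforms])


def _metric_value(a: np.ndarray, b: np.ndarray, metric: str, cc_radius) -> float:
    if metric == "ssd":
        return -float(np.mean((a - b) ** 2))
    if metric != "cc":
        raise ValueError("metric must be 'cc' or 'ssd'")
    if cc_radius:
        size = 2 * int(cc_radius) + 1
        a = a - ndimage.uniform_filter(a, size)
        b = b - ndimage.uniform_filter(b, size)
    av, bv = a.ravel(), b.ravel()
    sa, sb = av.std(), bv.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.dot(av - av.mean(), bv - bv.mean()) / (len(av) * sa * sb))


def _downsample(img: np.ndarray) -> np.ndarray:
    return ndimage.zoom(ndimage.gaussian_filter(img, 1.0), 0.5, order=1)


def register_rigid_2d(
    moving: np.ndarray,
    fixed: np.ndarray,
    pixel_size: float,
    metric: str = "cc",
    cc_radius: int = 0,
    init: RigidTransform2D = None,
    levels: int = 3,
    background: float = 0.0,
    translation_init: bool = True,
    max_rotation_deg: float = 25.0,
    max_translation_mm: float = None,
):
    """Multi-resolution rigid registration of ``moving`` onto ``fixed``.

    Returns ``(transform, metric_value)`` where the transform is the
    forward point map that brings moving features onto fixed features.
    The search is local: a phase-correlation exhaustive translation
    initialization at the coarsest level, then derivative-free (Powell)
    refinement of ``(theta, tx, ty)`` through the pyramid.
    ``max_translation_mm`` bounds the translation around the
    initialization; when the displacement scale is known (e.g. bounded
    mounting jitter) this keeps a low-contrast section from latching
    onto a spurious far-away optimum.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape:
        raise ValueError("moving and fixed must share shape and pixel size")
    center = image_center_mm(moving.shape, pixel_size)
    if init is None:
        T = RigidTransform2D.identity(center)
    else:
        if not np.allclose(init.center, center):
            raise ValueError("init transform must use the image-center convention")
        T = RigidTransform2D(init.theta, init.t.copy(), init.center.copy())

    pyr_m, pyr_f, pyr_ps = [moving], [fixed], [pixel_size]
    for _ in range(levels - 1):
        if min(pyr_m[-1].shape) < 16:
            break
        pyr_m.append(_downsample(pyr_m[-1]))
        pyr_f.append(_downsample(pyr_f[-1]))
        pyr_ps.append(pyr_ps[-1] * 2.0)

    theta, t = T.theta, T.t.copy()
    # the search is local: rotations are confined to a window around the
    # initialization so a low-contrast section cannot send the optimizer
    # to a spurious far-away optimum
    th_lo = T.theta - np.radians(max_rotation_deg)
    th_hi = T.theta + np.radians(max_rotation_deg)
    if max_translation_mm is None:
        t_lo, t_hi = np.full(2, -np.inf), np.full(2, np.inf)
    else:
        t_lo, t_hi = T.t - max_translation_mm, T.t + max_translation_mm
    for lvl in range(len(pyr_m) - 1, -1, -1):
        m_l, f_l, ps_l = pyr_m[lvl], pyr_f[lvl], pyr_ps[lvl]
        if np.ptp(m_l) == 0 or np.ptp(f_l) == 0:
            raise ValueError("empty overlap: image has no contrast at this level")
        if lvl == len(pyr_m) - 1 and translation_init:
            warped = apply_rigid_2d(
                m_l, RigidTransform2D(theta, t, center), ps_l, background=background
            )
            shift, _, _ = phase_cross_correlation(f_l, warped, normalization=None)
            # discard implausibly large offsets (spurious peaks on
            # near-empty sections); the local search takes over instead
            cand = t + shift * ps_l
            if np.linalg.norm(shift) <= 0.25 * min(m_l.shape) and np.all(
                (cand >= t_lo) & (cand <= t_hi)
            ):
                t = cand

        scale = np.array([0.02, 4 * ps_l, 4 * ps_l])  # rad, mm, mm per unit step

        def cost(x):
            Tx = RigidTransform2D(
                np.clip(theta + x[0] * scale[0], th_lo, th_hi),
                np.clip(t + x[1:] * scale[1:], t_lo, t_hi),
                center,
            )
            warped = apply_rigid_2d(m_l, Tx, ps_l, background=background)
            return -_metric_value(warped, f_l, metric, cc_radius)

        res = optimize.minimize(
            cost,
            np.zeros(3),
            method="Powell",
            options={"xtol": 1e-3, "ftol": 1e-7, "maxiter": 60},
        )
        theta = float(np.clip(theta + res.x[0] * scale[0], th_lo, th_hi))
        t = np.clip(t + res.x[1:] * scale[1:], t_lo, t_hi)

    final = RigidTransform2D(theta, t, center)
    warped = apply_rigid_2d(moving, final, pixel_size, background=background)
    value = _metric_value(warped, fixed, metric, cc_radius)
    return final, value


def align_blockface_stack(
    blockface: SectionSeries,
    ref_index: int,
    metric: str = "cc",
    levels: int = 2,
) -> TransformSeries:
    """Propagation alignment of the blockface stack.

    Rigid transforms between consecutive images are registered and
    serially composed from the reference section towards both ends; the
    reference transform is the identity.  A failed pairwise registration
    propagates the identity with a logged warning rather than aborting.
    """
    n = len(blockface)
    if not (0 <= ref_index < n):
        raise ValueError("ref_index out of range")
    ps = blockface.pixel_size
    secs = blockface.sections
    center = image_center_mm(secs[0].shape, ps)
    absolute = [None] * n
    absolute[ref_index] = RigidTransform2D.identity(center)
    for direction in (1, -1):
        i = ref_index + direction
        while 0 <= i < n:
            inner = i - direction
            try:
                P, _ = register_rigid_2d(
                    secs[i], secs[inner], ps, metric=metric, levels=levels
                )
            except Exception as exc:  # pragma: no cover - defensive path
                logger.warning("pairwise registration failed at section %d: %s", i, exc)
                P = RigidTransform2D.identity(center)
            absolute[i] = compose_rigid_2d(absolute[inner], P)
            i += direction
    return TransformSeries(absolute, ref_index)


def coarse_align_to_blockface(
    stained: SectionSeries,
    blockface_aligned: SectionSeries,
    metric: str = "cc",
    levels: int = 3,
    max_translation_mm: float = 0.8,
) -> TransformSeries:
    """Register every stained section to its blockface counterpart.

    Stained section ``i`` corresponds to blockface image
    ``interleave * i + parity``.  The returned transforms map each
    stained section into the (anatomy-true) blockface space.
    """
    n_bf = len(blockface_aligned)
    transforms = []
    for i, sec in enumerate(stained.sections):
        j = stained.physical_index(i)
        if j >= n_bf:
            raise ValueError(f"stained section {i} maps to blockface {j} >= {n_bf}")
        T, _ = register_rigid_2d(
            sec, blockface_aligned.sections[j], stained.pixel_size,
            metric=metric, levels=levels, max_translation_mm=max_translation_mm,
        )
        transforms.append(T)
    return TransformSeries(transforms, reference_index=0)


def fine_sequential_align(
    series: SectionSeries,
    center_index: int,
    channel: str = "gray",
    median_kernel: int = 5,
    metric: str = "cc",
    levels: int = 2,
) -> TransformSeries:
    """Sequential neighbor alignment outward from a central section.

    Sections are registered one by one to their already-aligned inner
    neighbor; registration operates on the selected channel smoothed
    with a median filter, but the returned absolute transforms apply to
    the original sections.  The central section's transform is the
    identity.
    """
    from .preprocess import _extract_channel

    n = len(series)
    if not (0 <= center_index < n):
        raise ValueError("center_index out of range")
    ps = series.pixel_size
    filt = [
        ndimage.median_filter(_extract_channel(s, channel), size=median_kernel)
        for s in series.sections
    ]
    center = image_center_mm(filt[0].shape, ps)
    absolute = [None] * n
    absolute[center_index] = RigidTransform2D.identity(center)
    for direction in (1, -1):
        i = center_index + direction
        while 0 <= i < n:
            inner = i - direction
            fixed_img = apply_rigid_2d(filt[inner], absolute[inner], ps)
            T, _ = register_rigid_2d(
                filt[i], fixed_img, ps, metric=metric,
                init=absolute[inner], levels=levels,
            )
            absolute[i] = T
            i += direction
    return TransformSeries(absolute, center_index)


def merge_coarse_fine(
    coarse: TransformSeries, fine: TransformSeries, sigma_sections: float = 5.0
) -> TransformSeries:
    """Frequency-split merge of the coarse and fine transform series.

    Each fine parameter profile (rotation angle, tx, ty) across the
    stack is Gaussian-smoothed (``sigma_sections``, reflective boundary,
    angles unwrapped first); the smoothed (low-frequency) part is
    discarded and the remaining high-frequency part is added to the
    coarse parameters.  ``sigma_sections = 0`` returns the coarse series
    unchanged (the smoothed copy equals the fine series).
    """
    if len(coarse) != len(fine):
        raise ValueError("coarse and fine series must have equal length")
    centers = np.stack([T.center for T in coarse.transforms])
    if not np.allclose(centers, centers[0]):
        raise ValueError("coarse transforms must share a rotation center")
    center = coarse.transforms[0].center
    for T in fine.transforms:
        if not np.allclose(T.center, center):
            raise ValueError("fine transforms must share the coarse center")

    pf = fine.parameters()
    pf[:, 0] = np.unwrap(pf[:, 0])
    if sigma_sections > 0:
        low = np.stack(
            [_lowpass_profile(pf[:, k], sigma_sections) for k in range(3)], axis=1
        )
    else:
        low = pf.copy()
    high = pf - low
    pc = coarse.parameters()
    merged = pc + high
    transforms = [
        RigidTransform2D(_wrap_angle(m[0]), m[1:].copy(), center.copy())
        for m in merged
    ]
    return TransformSeries(transforms, coarse.reference_index)


def _wrap_angle(theta: float) -> float:
    """Wrap into (-pi, pi); exact (bit-identical) when already inside."""
    if -np.pi < theta < np.pi:
        return float(theta)
    return float(np.arctan2(np.sin(theta), np.cos(theta)))


def _lowpass_profile(p: np.ndarray, sigma: float) -> np.ndarray:
    """Trend-preserving Gaussian low-pass of one parameter profile.

    A reflective-boundary Gaussian flattens linear trends near the stack
    ends, which would leak a spurious end-bend into the high-pass band;
    the linear trend is therefore removed first, the residual smoothed
    with reflective boundaries, and the trend restored.  Constant
    profiles are reproduced exactly.
    """
    if np.ptp(p) == 0:  # constant profiles are their own low-pass, exactly
        return p.copy()
    n = len(p)
    x = np.arange(n, dtype=float)
    slope, intercept = np.polyfit(x, p, 1)
    trend = slope * x + intercept
    return trend + ndimage.gaussian_filter1d(p - trend, sigma, mode="reflect")


def smooth_transform_series(
    series: TransformSeries, sigma_sections: float
) -> TransformSeries:
    """Gaussian-smooth each transform parameter profile along the stack.

    Used by the coarse-to-fine driver to keep only the low-frequency
    (anatomy) band of the coarse series: the per-section jitter band is
    supplied by the fine series in the merge, and keeping it in both
    would correct it twice.
    """
    if sigma_sections <= 0:
        return TransformSeries(
            [RigidTransform2D(T.theta, T.t.copy(), T.center.copy()) for T in series.transforms],
            series.reference_index,
        )
    center = series.transforms[0].center
    p = series.parameters()
    p[:, 0] = np.unwrap(p[:, 0])
    low = np.stack(
        [_lowpass_profile(p[:, k], sigma_sections) for k in range(3)], axis=1
    )
    transforms = [
        RigidTransform2D(_wrap_angle(m[0]), m[1:].copy(), center.copy())
        for m in low
    ]
    return TransformSeries(transforms, series.reference_index)


def coarse_to_fine_transforms(
    coarse: TransformSeries, fine: TransformSeries, sigma_sections: float = 5.0
) -> TransformSeries:
    """Frequency-split combination used for the final rigid reconstruction.

    The merged series takes its low-frequency band (anatomical trend,
    z-shift preservation) from the blockface-guided coarse series and
    its high-frequency band (section-to-section coherence) from the
    sequential fine series, both split with the same Gaussian kernel.
    """
    return merge_coarse_fine(
        smooth_transform_series(coarse, sigma_sections), fine, sigma_sections
    )


def apply_transform_series(
    series: SectionSeries, transforms: TransformSeries, interpolation: str = "linear"
) -> SectionSeries:
    """Resample every section under its transform."""
    if len(series) != len(transforms):
        raise ValueError("one transform per section required")
    out = [
        apply_rigid_2d(s, T, series.pixel_size, interpolation=interpolation)
        for s, T in zip(series.sections, transforms.transforms)
    ]
    return SectionSeries(
        out, series.pixel_size, series.thickness, series.interleave,
        series.parity, list(series.qc_flags),
    )


def reconstruct_rigid_volume(
    series: SectionSeries,
    transforms: TransformSeries = None,
    thickness: float = None,
) -> Volume3D:
    """Stack (optionally transformed) sections into a Volume3D.

    The stack axis is AP with spacing ``thickness * interleave``; the
    series parity offsets the stack origin by ``parity * thickness``.
    """
    if transforms is not None:
        series = apply_transform_series(series, transforms)
    thickness = series.thickness if thickness is None else thickness
    z_spacing = thickness * series.interleave
    vals = np.stack(series.sections, axis=1)
    spacing = np.array([series.pixel_size, z_spacing, series.pixel_size])
    origin = np.array([0.0, series.parity * thickness, 0.0])
    return Volume3D(vals, spacing, origin)
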