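"""Iterative deformable refinement of a rigidly reconstructed stack.

Each section is warped toward the average image of its nearest neighbor
sections; doing this for every section once constitutes one iteration,
and many iterations are applied with a schedule of progressively finer
parameters.  The per-pair registration is a greedy demons-style update
driven by a windowed (local) cross-correlation force:

1. intensities are locally normalized with the CC kernel radius,
2. the similarity gradient is smoothed (``sigma_gradient``, voxels),
3. the update is scaled so its largest magnitude equals
   ``gradient_step`` voxels and composed into the running field,
4. the composed field is smoothed (``sigma_field``, voxels).

Updates within one stack iteration are synchronous: every target is the
neighbor average of the *previous* iterate, so the result does not
depend on the order in which sections are processed.  Accumulated
fields are composed across iterations and applied once to the original
rigid-space sections, avoiding repeated resampling blur.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .transforms import compose_fields, jacobian_determinant, warp_with_field
from .types import DisplacementField, SectionSeries

__all__ = [
    "DeformableIteration",
    "DeformableSchedule",
    "register_deformable_2d",
    "neighbor_average_target",
    "deformable_reconstruct",
]


@dataclass
class DeformableIteration:
    """Parameters of one stack iteration.

    ``gradient_step`` is the maximum per-update displacement in voxels
    (0.15-0.5), ``cc_radius`` the CC kernel radius in pixels (4 or 16
    for the reconstruction stage), ``sigma_gradient`` / ``sigma_field``
    the Gaussian regularization of the similarity gradient and of the
    displacement field in voxels.
    """

    gradient_step: float = 0.25
    cc_radius: int = 4
    sigma_gradient: float = 3.0
    sigma_field: float = 1.0
    neighbor_radius: int = 1
    inner_iterations: int = 8

    def __post_init__(self):
        if not (0.0 < self.gradient_step <= 1.0):
            raise ValueError("gradient_step must be in (0, 1]")
        if self.sigma_gradient < 0 or self.sigma_field < 0:
            raise ValueError("sigmas must be >= 0")
        if self.neighbor_radius < 1:
            raise ValueError("neighbor_radius must be >= 1")


@dataclass
class DeformableSchedule:
    """Ordered list of stack iterations."""

    iterations: list

    def __post_init__(self):
        if not self.iterations:
            raise ValueError("schedule needs at least one iteration")

    def __len__(self) -> int:
        return len(self.iterations)

    @staticmethod
    def default(n_iterations: int = 10) -> "DeformableSchedule":
        """Coarse-to-fine default: early iterations take large steps with
        a wide CC kernel, late iterations small steps with a narrow one."""
        its = []
        for k in range(n_iterations):
            early = k < n_iterations // 2
            its.append(
                DeformableIteration(
                    gradient_step=0.5 if early else 0.15,
                    cc_radius=16 if early else 4,
                )
            )
        return DeformableSchedule(its)

    @staticmethod
    def from_dicts(entries) -> "DeformableSchedule":
        return DeformableSchedule([DeformableIteration(**e) for e in entries])


def _local_normalize(img: np.ndarray, radius: int) -> np.ndarray:
    size = 2 * int(radius) + 1
    mean = ndimage.uniform_filter(img, size)
    var = ndimage.uniform_filter(img**2, size) - mean**2
    # variance floor keeps flat background flat instead of amplifying
    # interpolation ripples into spurious structure
    floor = (0.05 * img.std()) ** 2 + 1e-12
    return (img - mean) / np.sqrt(np.maximum(var, floor))


def _cc_metric(a: np.ndarray, b: np.ndarray) -> float:
    av, bv = a.ravel(), b.ravel()
    sa, sb = av.std(), bv.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.dot(av - av.mean(), bv - bv.mean()) / (len(av) * sa * sb))


def register_deformable_2d(
    moving: np.ndarray,
    fixed: np.ndarray,
    params: DeformableIteration,
    pixel_size: float = 1.0,
    init_field: DisplacementField = None,
) -> DisplacementField:
    """Greedy deformable registration of ``moving`` toward ``fixed``.

    Returns a pull-back field on the fixed grid so that
    ``warp_with_field(moving, field) ~ fixed``.  Stops early and returns
    the best field seen if the similarity worsens 5 updates in a row.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape:
        raise ValueError("moving and fixed must share a grid")
    spacing = np.array([pixel_size, pixel_size])
    field = (
        DisplacementField.zero(moving.shape, spacing)
        if init_field is None
        else DisplacementField(init_field.vectors.copy(), spacing)
    )
    nf = _local_normalize(fixed, params.cc_radius)
    best_field = field
    best_metric = -np.inf
    worse_streak = 0
    for _ in range(params.inner_iterations):
        warped = warp_with_field(moving, field)
        nw = _local_normalize(warped, params.cc_radius)
        metric = _cc_metric(nw, nf)
        if metric > best_metric + 1e-12:
            best_metric = metric
            best_field = DisplacementField(field.vectors.copy(), spacing)
            worse_streak = 0
        else:
            worse_streak += 1
            if worse_streak >= 5:
                break
        # demons force on locally normalized intensities
        gx, gy = np.gradient(nw)
        gmag2 = gx**2 + gy**2
        diff = nf - nw
        denom = gmag2 + np.mean(diff**2) + 1e-8
        ux = diff * gx / denom
        uy = diff * gy / denom
        if params.sigma_gradient > 0:
            ux = ndimage.gaussian_filter(ux, params.sigma_gradient)
            uy = ndimage.gaussian_filter(uy, params.sigma_gradient)
        mag = np.sqrt(ux**2 + uy**2)
        peak = mag.max()
        if peak < 1e-12:
            break
        scale = params.gradient_step / peak  # cap update at gradient_step voxels
        delta = np.stack([ux, uy], axis=-1) * scale * pixel_size
        update = DisplacementField(delta, spacing)
        field = compose_fields(update, field)
        if params.sigma_field > 0:
            vec = np.stack(
                [
                    ndimage.gaussian_filter(field.vectors[..., a], params.sigma_field)
                    for a in range(2)
                ],
                axis=-1,
            )
            field = DisplacementField(vec, spacing)
    warped = warp_with_field(moving, field)
    final_metric = _cc_metric(_local_normalize(warped, params.cc_radius), nf)
    return field if final_metric >= best_metric else best_field


def neighbor_average_target(
    series_or_images, i: int, neighbor_radius: int = 1
) -> np.ndarray:
    """Unweighted mean of up to ``neighbor_radius`` sections on each side
    of ``i`` (excluding ``i`` itself); one-sided at the stack ends."""
    if neighbor_radius < 1:
        raise ValueError("neighbor_radius must be >= 1")
    images = (
        series_or_images.sections
        if isinstance(series_or_images, SectionSeries)
        else series_or_images
    )
    n = len(images)
    idx = [
        j
        for j in range(i - neighbor_radius, i + neighbor_radius + 1)
        if 0 <= j < n and j != i
    ]
    if not idx:
        raise ValueError("no neighbors available")
    return np.mean([np.asarray(images[j], dtype=float) for j in idx], axis=0)


def deformable_reconstruct(
    series: SectionSeries, schedule: DeformableSchedule
):
    """Iteratively warp every section toward its neighbor average.

    Returns ``(refined_series, fields, smoothness_history)``: the warped
    sections, the accumulated per-section pull-back fields (rigid-space
    section -> refined section), and the neighbor-dissimilarity score
    ``S = mean_i (1 - CC(I_i, I_{i+1}))`` evaluated before the first and
    after every iteration.
    """
    if not isinstance(schedule, DeformableSchedule) or len(schedule) == 0:
        raise ValueError("a non-empty DeformableSchedule is required")
    ps = series.pixel_size
    spacing = np.array([ps, ps])
    originals = [np.asarray(s, dtype=float) for s in series.sections]
    n = len(originals)
    fields = [DisplacementField.zero(originals[0].shape, spacing) for _ in range(n)]
    current = [img.copy() for img in originals]
    history = [_stack_dissimilarity(current)]
    for params in schedule.iterations:
        new_fields = []
        for i in range(n):
            target = neighbor_average_target(current, i, params.neighbor_radius)
            updated = register_deformable_2d(
                originals[i], target, params, pixel_size=ps, init_field=fields[i]
            )
            # greedy acceptance: an update that worsens the section's
            # plain correlation to its target is discarded, keeping the
            # stack dissimilarity from creeping back up late in the run
            cc_old = _cc_metric(current[i], target)
            cc_new = _cc_metric(warp_with_field(originals[i], updated), target)
            new_fields.append(updated if cc_new >= cc_old else fields[i])
        fields = new_fields
        current = [warp_with_field(originals[i], fields[i]) for i in range(n)]
        history.append(_stack_dissimilarity(current))
    refined = SectionSeries(
        current, ps, series.thickness, series.interleave, series.parity,
        list(series.qc_flags),
    )
    return refined, fields, np.array(history)


def _stack_dissimilarity(images) -> float:
    """S = mean over consecutive pairs of (1 - Pearson CC)."""
    vals = [
        1.0 - _cc_metric(np.asarray(images[i], dtype=float), np.asarray(images[i + 1], dtype=float))
        for i in range(len(images) - 1)
    ]
    return float(np.mean(vals))


def negative_jacobian_fraction(field: DisplacementField) -> float:
    """Fraction of pixels where the warp folds (negative Jacobian)."""
    return float(np.mean(jacobian_determinant(field) <= 0))
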