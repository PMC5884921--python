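"""Landmark-based accuracy evaluation and stereotaxic frame construction.

Registration accuracy is summarized by order statistics (5th percentile,
quartiles, median, 95th percentile) of Euclidean distances between
homologous landmarks.  The stereotaxic frame is built from cranial
landmarks — bregma, lambda and the interaural line — by reorienting the
head so bregma and lambda share a horizontal plane and the midsagittal
plane, the convention used in small-animal stereotaxy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import AffineTransform3D, LandmarkSet, Volume3D

__all__ = [
    "DiscrepancyStats",
    "StereotaxicFrame",
    "landmark_discrepancy",
    "build_stereotaxic_frame",
    "to_stereotaxic",
    "fit_brain_to_braincase",
    "rod_centroids_from_volume",
    "rod_straightness",
]


@dataclass
class DiscrepancyStats:
    """Order statistics of landmark distances, in mm."""

    p5: float
    q1: float
    median: float
    q3: float
    p95: float
    n: int

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not (self.p5 <= self.q1 <= self.median <= self.q3 <= self.p95):
            raise ValueError("percentiles must be ordered")

    def as_dict(self) -> dict:
        return {
            "p5": self.p5, "q1": self.q1, "median": self.median,
            "q3": self.q3, "p95": self.p95, "n": self.n,
        }


def landmark_discrepancy(A: LandmarkSet, B: LandmarkSet):
    """Per-landmark Euclidean distances between homologous points.

    Landmarks are matched by name (order-independent); a name mismatch
    is rejected listing the offenders.  Returns ``(distances, stats)``
    with distances ordered as in ``A``; percentiles use linear
    interpolation between order statistics.
    """
    names_a, names_b = set(A.names), set(B.names)
    if names_a != names_b:
        missing = sorted(names_a ^ names_b)
        raise ValueError(f"landmark name mismatch: {missing[:10]}")
    lookup = {n: c for n, c in zip(B.names, B.coords)}
    other = np.stack([lookup[n] for n in A.names])
    distances = np.linalg.norm(A.coords - other, axis=1)
    p5, q1, med, q3, p95 = np.percentile(distances, [5, 25, 50, 75, 95])
    stats = DiscrepancyStats(float(p5), float(q1), float(med), float(q3), float(p95), len(distances))
    return distances, stats


@dataclass
class StereotaxicFrame:
    """Rigid reorientation into stereotaxic axes.

    ``rigid`` maps world points into frame coordinates (ML, AP, DV) with
    AP positive anterior, ML positive right, DV positive dorsal.  The
    named landmark positions are stored in frame coordinates; reference
    origins are applied by :func:`to_stereotaxic`.  By construction
    bregma and lambda share their DV and their ML coordinate.
    """

    rigid: AffineTransform3D
    bregma: np.ndarray
    lam: np.ndarray
    interaural_midpoint: np.ndarray
    inclination_deg: float

    def __post_init__(self):
        if abs(self.bregma[2] - self.lam[2]) > 1e-6:
            raise ValueError("bregma and lambda must share the DV coordinate")
        if abs(self.bregma[0] - self.lam[0]) > 1e-6:
            raise ValueError("bregma and lambda must share the ML coordinate")


def build_stereotaxic_frame(
    bregma, lam, interaural_left, interaural_right
) -> StereotaxicFrame:
    """Construct the stereotaxic frame from four cranial points (world mm).

    The AP axis runs from lambda to bregma (bregma anterior), the ML
    axis along the interaural line component orthogonal to AP, and DV
    completes the right-handed (ML, AP, DV) triad.  The reported
    inclination is the pitch needed to level bregma and lambda: the
    angle between the bregma-lambda segment and its projection onto the
    original horizontal plane.
    """
    bregma = np.asarray(bregma, dtype=float)
    lam = np.asarray(lam, dtype=float)
    ia_l = np.asarray(interaural_left, dtype=float)
    ia_r = np.asarray(interaural_right, dtype=float)
    ap_vec = bregma - lam
    if np.linalg.norm(ap_vec) < 1e-9:
        raise ValueError("bregma and lambda coincide")
    if np.linalg.norm(ia_r - ia_l) < 1e-9:
        raise ValueError("interaural points coincide")
    ap = ap_vec / np.linalg.norm(ap_vec)
    ml_raw = ia_r - ia_l
    ml = ml_raw - (ml_raw @ ap) * ap
    if np.linalg.norm(ml) < 1e-9:
        raise ValueError("interaural line is collinear with the AP axis")
    ml /= np.linalg.norm(ml)
    dv = np.cross(ml, ap)
    R = np.stack([ml, ap, dv])  # rows: frame axes in world coordinates
    rigid = AffineTransform3D(R, np.zeros(3))

    horiz = ap_vec.copy()
    horiz[2] = 0.0
    inclination = float(
        np.degrees(np.arctan2(abs(ap_vec[2]), np.linalg.norm(horiz)))
    )
    frame = StereotaxicFrame(
        rigid=rigid,
        bregma=rigid.apply_points(bregma)[0],
        lam=rigid.apply_points(lam)[0],
        interaural_midpoint=rigid.apply_points(0.5 * (ia_l + ia_r))[0],
        inclination_deg=inclination,
    )
    return frame


def to_stereotaxic(point, frame: StereotaxicFrame, reference: str = "bregma"):
    """Express a world point as (ML, AP, DV) mm relative to a reference.

    ``reference`` is one of ``bregma``, ``lambda`` or ``interaural``
    (the midpoint of the interaural line).  AP is positive anterior, ML
    positive right, DV positive dorsal.
    """
    origins = {
        "bregma": frame.bregma,
        "lambda": frame.lam,
        "interaural": frame.interaural_midpoint,
    }
    if reference not in origins:
        raise ValueError(f"unknown reference {reference!r}; use {sorted(origins)}")
    pt = np.asarray(point, dtype=float)
    framed = frame.rigid.apply_points(pt)
    out = framed - origins[reference]
    return out[0] if pt.ndim == 1 else out


def fit_brain_to_braincase(
    brain_mask: Volume3D, braincase_mask: Volume3D
):
    """Rigid fit of the brain mask into the braincase mask.

    Delegates to the SSD mask registration with rigid degrees of
    freedom; additionally reports the fraction of brain voxels left
    outside the braincase after the fit (0 for a contained fit).
    Returns ``(transform, uncovered_fraction)``.
    """
    import warnings

    from .coreg import affine_register_masks, resample_mask_through_affine

    if braincase_mask.values.sum() < brain_mask.values.sum():
        raise ValueError("braincase mask must be at least as large as the brain mask")
    T = affine_register_masks(brain_mask, braincase_mask, dof="rigid")
    moved = resample_mask_through_affine(brain_mask, T, braincase_mask)
    inside = float(np.sum((moved.values > 0.5) & (braincase_mask.values > 0.5)))
    total = float(np.sum(moved.values > 0.5))
    uncovered = 0.0 if total == 0 else 1.0 - inside / total
    if uncovered > 0.2:
        warnings.warn(f"{uncovered:.0%} of the brain lies outside the braincase after fit")
    return T, uncovered


def rod_centroids_from_volume(
    volume: Volume3D, threshold_fraction: float = 0.75, min_pixels: int = 3
) -> np.ndarray:
    """Per-section centroid track of the brightest structure (the rod probe).

    For every section along the stack (AP) axis the slice is thresholded
    at ``threshold_fraction`` of its *own* maximum — robust against
    slice-to-slice intensity drift — and the connected component
    containing the brightest pixel is kept; its intensity-weighted
    centroid in world mm forms one track point.  Sections with fewer
    than ``min_pixels`` suprathreshold pixels yield NaN rows.
    """
    from scipy import ndimage as ndi

    vals = volume.values if volume.values.ndim == 3 else volume.values.mean(axis=-1)
    n = vals.shape[1]
    out = np.full((n, 3), np.nan)
    for i in range(n):
        sl = vals[:, i, :]
        smax = sl.max()
        if smax <= 0:
            continue
        mask = sl >= threshold_fraction * smax
        labels, nlab = ndi.label(mask, structure=np.ones((3, 3), dtype=bool))
        if nlab == 0:
            continue
        peak = np.unravel_index(np.argmax(sl), sl.shape)
        comp = labels == labels[peak]
        if comp.sum() < min_pixels:
            continue
        w = sl[comp]
        idx = np.argwhere(comp)
        c = (idx * w[:, None]).sum(axis=0) / w.sum()
        out[i] = volume.origin + np.array([c[0], i, c[1]]) * volume.spacing
    return out


def rod_straightness(points: np.ndarray):
    """Straightness of a per-section centroid track.

    ``points`` is ``(n, 3)`` (mm, one per section; NaN rows ignored).
    A total-least-squares line is fitted; returns a dict with
    ``tilt_deg`` — the angle between the line and the stack (AP) axis —
    and ``max_deviation_mm`` — the largest orthogonal residual.
    """
    pts = np.asarray(points, dtype=float)
    pts = pts[~np.any(np.isnan(pts), axis=1)]
    if len(pts) < 3:
        raise ValueError("need at least 3 finite points")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    axis = np.zeros(3)
    axis[1] = 1.0  # stack axis (AP)
    cosang = abs(direction @ axis) / np.linalg.norm(direction)
    tilt = float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))
    residual = centered - np.outer(centered @ direction, direction)
    return {
        "tilt_deg": tilt,
        "max_deviation_mm": float(np.max(np.linalg.norm(residual, axis=1))),
    }
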