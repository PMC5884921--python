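"""Section-level cleanup: masking, QC, replacement, intensity correction.

These are the steps applied to digitized stained sections before any
registration: extracting a tissue mask per section, flagging and
replacing distorted sections with their nearest intact neighbors,
slice-to-slice staining-intensity correction by weighted histogram
matching, 3D unsharp masking for contrast, and a simple KMeans tissue
classifier.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .types import SectionSeries, Volume3D

__all__ = [
    "make_tissue_mask_2d",
    "make_tissue_mask_3d",
    "flag_distorted_auto",
    "replace_distorted",
    "histogram_match_series",
    "unsharp_3d",
    "kmeans_tissue_classes",
]

_STRUCT_2D = np.ones((3, 3), dtype=bool)  # 8-connectivity
_STRUCT_3D = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity


def _extract_channel(image: np.ndarray, channel: str) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        return image
    if image.ndim == 3 and image.shape[-1] == 3:
        if channel == "red":
            return image[..., 0]
        return image.mean(axis=-1)
    raise ValueError("image must be 2D grayscale or 2D RGB")


def _largest_component(binary: np.ndarray, structure: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(binary, structure=structure)
    if n == 0:
        raise ValueError("no foreground pixels on the tissue side of the threshold")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return (labels == counts.argmax()).astype(np.uint8)


def make_tissue_mask_2d(
    image: np.ndarray,
    channel: str = "gray",
    median_kernel: int = 5,
    threshold_fraction: float = 0.948,
    tissue_is_dark: bool = True,
) -> np.ndarray:
    """Tissue mask of one section: median filter, fractional threshold,
    largest connected component.

    The selected channel is smoothed with a ``median_kernel`` square
    median filter and thresholded at ``threshold_fraction`` of the
    *filtered* image maximum.  ``tissue_is_dark`` picks the threshold
    side: scanned stained sections show dark tissue on a light
    background (take pixels below the threshold), while phantoms and
    blockface photos are bright-on-dark (take pixels above).  The mask
    is the largest 8-connected component of the selected pixels.
    """
    chan = _extract_channel(image, channel)
    if np.ptp(chan) == 0:
        raise ValueError("constant image: no tissue/background contrast")
    filtered = ndimage.median_filter(chan, size=median_kernel)
    thresh = threshold_fraction * filtered.max()
    binary = filtered < thresh if tissue_is_dark else filtered > thresh
    return _largest_component(binary, _STRUCT_2D)


def make_tissue_mask_3d(
    volume: Volume3D, threshold_fraction: float = 0.5, tissue_is_dark: bool = False
) -> Volume3D:
    """Largest 26-connected component above/below a fractional threshold."""
    vals = volume.values if volume.values.ndim == 3 else volume.values.mean(axis=-1)
    if np.ptp(vals) == 0:
        raise ValueError("constant volume")
    thresh = threshold_fraction * vals.max()
    binary = vals < thresh if tissue_is_dark else vals > thresh
    return volume.with_values(_largest_component(binary, _STRUCT_3D).astype(float))


def _aligned_corr(a: np.ndarray, b: np.ndarray, pixel_size: float = 1.0) -> float:
    """Foreground correlation after compensating the mounting jitter.

    Raw neighboring sections are displaced by rigid mounting jitter of
    the same magnitude as the distortions being screened for, so the
    pair is first rigidly registered; what correlation the alignment
    cannot recover is non-rigid distortion.  The correlation is
    computed over the union of the two foregrounds only: for small
    sections near the specimen poles the background would otherwise
    dominate and mask internal distortion.
    """
    from .rigid import register_rigid_2d
    from .transforms import apply_rigid_2d

    if a.std() == 0 or b.std() == 0:
        return 1.0
    # mild pre-smoothing: thin structures (one-two pixel cell layers)
    # decorrelate between neighboring sections for purely anatomical
    # reasons; damage displaces tissue on a much larger scale
    a = ndimage.gaussian_filter(a, 1.5)
    b = ndimage.gaussian_filter(b, 1.5)
    try:
        T, _ = register_rigid_2d(a, b, pixel_size, levels=2)
    except ValueError:
        return 1.0
    a_al = apply_rigid_2d(a, T, pixel_size)
    thresh = 0.05 * max(a_al.max(), b.max())
    fg = (a_al > thresh) | (b > thresh)
    if fg.sum() < 16:
        return 1.0
    av, bv = a_al[fg], b[fg]
    if av.std() == 0 or bv.std() == 0:
        return 1.0
    return float(np.corrcoef(av, bv)[0, 1])


def flag_distorted_auto(series: SectionSeries, z_thresh: float = 3.0) -> list:
    """Flag sections that are robust-z outliers in neighbor similarity.

    Each section is compared with its neighbors at distance one and two
    on each side by rigid-alignment-compensated foreground correlation;
    the per-section statistic is the best of those (a distorted section
    is dissimilar to *all* of them, while an intact section adjacent to
    a run of damaged ones still matches a clean neighbor two sections
    away).  A running-median baseline excluding the section itself
    absorbs the gradual anatomy change toward the specimen poles, and
    sections whose residual falls more than ``z_thresh`` robust
    standard deviations below the baseline are flagged.  Sections whose
    tissue area is under 40% of the largest section abstain: at the
    poles anatomy changes faster than any damage signal.
    """
    n = len(series)
    if n < 5:
        raise ValueError("need at least 5 sections for auto QC")
    secs = [np.asarray(s, dtype=float) for s in series.sections]
    if series.sections[0].ndim == 3:
        secs = [s.mean(axis=-1) for s in secs]
    # best similarity over neighbors at distance 1 and 2 on each side: a
    # damaged section is dissimilar to all of them, while a clean one
    # next to (even a run of) damaged sections still matches a clean
    # neighbor two sections away
    cache = {}

    def corr(i, j):
        key = (min(i, j), max(i, j))
        if key not in cache:
            cache[key] = _aligned_corr(secs[key[0]], secs[key[1]], series.pixel_size)
        return cache[key]

    stat = np.empty(n)
    for i in range(n):
        cands = [corr(i, j) for j in (i - 2, i - 1, i + 1, i + 2) if 0 <= j < n]
        stat[i] = max(cands)
    # local baseline excluding the section itself, so an outlier at the
    # stack end cannot drag its own baseline down
    baseline = np.empty(n)
    for i in range(n):
        nb = [stat[j] for j in range(i - 2, i + 3) if 0 <= j < n and j != i]
        baseline[i] = np.median(nb)
    resid = stat - baseline
    # damage can only lower the statistic, so the noise scale is
    # estimated from the uncontaminated positive residuals
    pos = resid[resid > 0]
    scale = 1.2533 * float(np.mean(pos)) if pos.size else 0.0
    # absolute floor: correlation drops below half a percent are within
    # measurement granularity regardless of how quiet the stack is
    scale = max(scale, 5e-3)
    z = resid / scale
    # sections near the specimen poles hold too little tissue for the
    # neighbor-similarity statistic to be meaningful: their anatomy
    # changes faster than any damage signal, so auto-QC abstains there
    areas = np.array([np.sum(s > 0.05 * s.max()) if s.max() > 0 else 0 for s in secs])
    judgeable = areas >= 0.4 * areas.max()
    return [bool(z[i] < -z_thresh and judgeable[i]) for i in range(n)]


def replace_distorted(series: SectionSeries, qc_flags=None):
    """Replace flagged sections with their nearest unflagged neighbor.

    Ties in distance are broken toward the lower index.  Returns the
    repaired series and the replacement map ``{flagged: source}``.
    Unflagged sections are passed through untouched.
    """
    flags = list(series.qc_flags if qc_flags is None else qc_flags)
    n = len(series)
    if len(flags) != n:
        raise ValueError("one flag per section required")
    good = [i for i in range(n) if not flags[i]]
    if not good:
        raise ValueError("all sections flagged: nothing to replace from")
    good_arr = np.array(good)
    replacement_map = {}
    out = []
    for i in range(n):
        if flags[i]:
            dist = np.abs(good_arr - i)
            src = int(good_arr[np.argmin(dist)])  # argmin → lowest index on tie
            replacement_map[i] = src
            out.append(series.sections[src].copy())
        else:
            out.append(series.sections[i].copy())
    repaired = SectionSeries(
        out,
        series.pixel_size,
        series.thickness,
        series.interleave,
        series.parity,
        [False] * n,
    )
    return repaired, replacement_map


def _histogram_cdf(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    hist, _ = np.histogram(values, bins=edges)
    cdf = np.cumsum(hist).astype(float)
    return cdf / cdf[-1]


def histogram_match_series(
    series: SectionSeries,
    window_sigma: float = 5.0,
    n_bins: int = 256,
    background: float = 0.0,
) -> SectionSeries:
    """Slice-to-slice staining-intensity correction by weighted histogram
    matching.

    Each section is monotonically remapped (CDF matching) toward the
    Gaussian-weighted average histogram of its neighborhood along the
    stack (``window_sigma`` in sections).  Pixels at the declared
    ``background`` value are excluded from the histograms and passed
    through unchanged: sections near the specimen poles are mostly
    background, and letting that mass into the CDFs would drag their
    tissue intensities (and the background itself) to spurious levels.
    Degenerate single-intensity sections pass through unchanged.  The
    mapping is nondecreasing, so tissue pixel rank order is preserved.
    """
    if window_sigma <= 0:
        raise ValueError("window_sigma must be positive")
    n = len(series)
    secs = [np.asarray(s, dtype=float) for s in series.sections]
    fgs = [~np.isclose(s, background) for s in secs]
    fg_vals = [s[m] for s, m in zip(secs, fgs)]
    usable = [v for v in fg_vals if v.size]
    if not usable:
        return series.copy()
    lo = min(v.min() for v in usable)
    hi = max(v.max() for v in usable)
    if hi == lo:
        return series.copy()
    edges = np.linspace(lo, hi, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    hists = np.stack(
        [
            np.histogram(v, bins=edges)[0].astype(float) if v.size else np.zeros(n_bins)
            for v in fg_vals
        ]
    )
    idx = np.arange(n)
    out = []
    for i in range(n):
        if fg_vals[i].size == 0 or np.ptp(fg_vals[i]) == 0:
            out.append(secs[i].copy())
            continue
        w = np.exp(-0.5 * ((idx - i) / window_sigma) ** 2)
        w /= w.sum()
        target_hist = w @ hists
        if target_hist.sum() == 0:
            out.append(secs[i].copy())
            continue
        target_cdf = np.cumsum(target_hist)
        target_cdf /= target_cdf[-1]
        src_cdf = _histogram_cdf(fg_vals[i], edges)
        # monotone value map: source quantile -> target quantile
        mapped_centers = np.interp(src_cdf, target_cdf, centers)
        sec = secs[i].copy()
        sec[fgs[i]] = np.interp(fg_vals[i], centers, mapped_centers)
        out.append(sec)
    return SectionSeries(
        out,
        series.pixel_size,
        series.thickness,
        series.interleave,
        series.parity,
        list(series.qc_flags),
    )


def unsharp_3d(
    volume: Volume3D, sigma: float, amount: float, clip: bool = False
) -> Volume3D:
    """3D unsharp mask: ``out = in + amount * (in - G_sigma(in))``.

    ``sigma`` is in mm and converted per axis through the voxel spacing.
    With ``clip`` the output is clamped to the input range.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if amount < 0:
        raise ValueError("amount must be >= 0")
    sig_vox = sigma / volume.spacing
    vals = volume.values
    if vals.ndim == 4:
        blurred = np.stack(
            [ndimage.gaussian_filter(vals[..., c], sig_vox) for c in range(vals.shape[-1])],
            axis=-1,
        )
    else:
        blurred = ndimage.gaussian_filter(vals, sig_vox)
    out = vals + amount * (vals - blurred)
    if clip:
        out = np.clip(out, vals.min(), vals.max())
    return volume.with_values(out)


def kmeans_tissue_classes(volume: Volume3D, k: int = 4, seed: int = 0) -> Volume3D:
    """Intensity-only KMeans tissue classification into ``k`` classes.

    Labels are relabeled so class means are strictly increasing with
    intensity (0 = darkest).  Deterministic for a fixed seed.
    """
    from sklearn.cluster import KMeans

    if k < 2:
        raise ValueError("k must be >= 2")
    vals = volume.values if volume.values.ndim == 3 else volume.values.mean(axis=-1)
    flat = vals.reshape(-1, 1)
    if len(np.unique(flat)) < k:
        raise ValueError("fewer distinct intensities than classes")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    raw = km.fit_predict(flat)
    order = np.argsort(km.cluster_centers_.ravel())
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    return volume.with_values(relabel[raw].reshape(vals.shape).astype(float))
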