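"""Synthetic sectioned-specimen phantom with full ground truth.

The phantom emulates the data situation of a serial-section histology
study: a smooth multi-channel 3D specimen is cut into thin coronal
sections collected into alternating staining series, while an undistorted
blockface photograph of the cut surface is kept for every section.  Each
stained section is corrupted by

* per-section rigid jitter (mounting of the section on the slide),
* a smooth per-section elastic distortion (cutting/staining),
* slice-to-slice multiplicative intensity drift, optionally with a
  period-3 alternation emulating batch-staining "chattering",
* a configurable fraction of "damaged" sections whose elastic distortion
  is several times the nominal amplitude.

The blockface series carries only a small per-section camera/cryostat
jitter.  The specimen body is deliberately *oblique*: its center drifts
linearly along the stack axis and a thin bright rod runs along that
oblique axis.  Purely section-to-section alignment straightens this drift
away (the z-shift / banana effect); a blockface-guided reconstruction
must preserve it.  The rod is the quantitative probe for this.

All randomness flows through one seeded generator; the truth bundle
records every per-section transform, field and landmark.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .transforms import apply_rigid_2d, compose_fields, warp_with_field
from .types import (
    DisplacementField,
    LandmarkSet,
    RigidTransform2D,
    SectionSeries,
    Volume3D,
)

__all__ = ["PhantomSpec", "PhantomTruth", "make_phantom_volume", "section_phantom"]

STAIN_CHANNELS = ("nissl", "myelin")


@dataclass
class PhantomSpec:
    """Parameters of the synthetic specimen and its simulated sectioning.

    Geometric scales are mm.  ``shear`` is the lateral drift of the body
    center per mm of stack depth — the obliqueness the rod probes.
    Jitter defaults (0.2 mm translation, 2 deg rotation) represent a
    plausible slide-mounting scatter of a few voxels at 40 um/voxel;
    blockface camera jitter is an order of magnitude smaller.
    """

    grid_shape: tuple = (64, 60, 64)
    spacing: float = 0.04
    radii: tuple = None  # mm, ellipsoid semi-axes (ML, AP, DV); default ~1/3 extent
    layer_radius_frac: float = 0.70  # thin bright internal layer (dentate-like)
    layer_thickness: float = 0.08  # mm
    shear: tuple = (0.25, 0.10)  # (d ML, d DV) per mm AP
    rod_radius: float = 0.10  # mm
    jitter_sigma_trans: float = 0.2  # mm, per-section stained rigid jitter
    jitter_sigma_rot: float = 2.0  # deg
    blockface_jitter_trans: float = 0.02  # mm, camera jitter
    blockface_jitter_rot: float = 0.2  # deg
    elastic_amplitude: float = 0.05  # mm RMS of the per-section field
    elastic_corr: float = 0.4  # mm correlation length
    shrink_factor: float = 0.96  # smooth staining shrinkage (in-plane)
    shrink_mod: float = 0.02  # slow modulation of the shrinkage along AP
    damaged_fraction: float = 0.10
    damaged_factor: float = 5.0
    drift_sigma: float = 0.15  # log-scale slice-to-slice drift
    chatter_amplitude: float = 0.08  # period-3 staining alternation
    chatter: bool = True
    interleave: int = 2
    cut_full_range: bool = False  # cut every slice, even tissue-free ones
    n_landmarks: int = 100
    texture_amplitude: float = 0.08  # smooth intra-tissue intensity texture
    seed: int = 0

    def __post_init__(self):
        if self.spacing <= 0 or self.elastic_corr <= 0 or self.layer_thickness <= 0:
            raise ValueError("all scales must be positive")
        if self.radii is None:
            # distinct per-axis radii: a rotationally degenerate (near-
            # spherical) specimen would make mask registration ill-posed
            ext = self.extent_mm()
            self.radii = (0.34 * ext[0], 0.40 * ext[1], 0.27 * ext[2])
        if not (0 <= self.damaged_fraction < 0.5):
            raise ValueError("damaged_fraction must be in [0, 0.5)")
        if self.interleave < 1:
            raise ValueError("interleave must be >= 1")
        for p in self.rod_endpoints():
            if np.any(p < 0) or np.any(p > self.extent_mm()):
                raise ValueError("rod endpoints must lie inside the grid")

    def extent_mm(self) -> np.ndarray:
        return np.array(self.grid_shape) * self.spacing

    def center_mm(self) -> np.ndarray:
        return (np.array(self.grid_shape) - 1) / 2.0 * self.spacing

    def body_center_at(self, y_mm: float) -> np.ndarray:
        """Body center in the section plane (ML, DV) at stack depth y."""
        c = self.center_mm()
        dy = y_mm - c[1]
        return np.array([c[0] + self.shear[0] * dy, c[2] + self.shear[1] * dy])

    def rod_endpoints(self) -> tuple:
        """The rod runs along the sheared body axis through the specimen."""
        c = self.center_mm()
        half = 0.9 * self.radii[1]
        p0 = np.array(
            [
                c[0] - self.shear[0] * half,
                c[1] - half,
                c[2] - self.shear[1] * half,
            ]
        )
        p1 = np.array(
            [
                c[0] + self.shear[0] * half,
                c[1] + half,
                c[2] + self.shear[1] * half,
            ]
        )
        return p0, p1

    def true_rod_tilt_deg(self) -> float:
        """Angle between the rod and the stack (AP) axis."""
        p0, p1 = self.rod_endpoints()
        d = p1 - p0
        lateral = np.hypot(d[0], d[2])
        return float(np.degrees(np.arctan2(lateral, abs(d[1]))))


@dataclass
class PhantomTruth:
    """Ground truth emitted by :func:`section_phantom`."""

    rigid: list  # per physical section, stained-section jitter
    fields: list  # per physical section, elastic DisplacementField (2D)
    blockface_rigid: list  # per section, camera jitter
    damaged: np.ndarray  # sorted physical indices
    drift: np.ndarray  # per-section multiplicative factor
    clean: dict  # channel name -> Volume3D (incl. "mask")
    landmarks: LandmarkSet
    rod_centroids: np.ndarray  # (n_sections, 2) mm (ML, DV); NaN off-rod
    section_offset: int = 0  # volume AP index of physical cut 0
    seed: int = 0


def _smooth_noise_field(rng, shape, pixel_size, amplitude, corr_mm):
    """Smoothed white-noise vector field with RMS magnitude ``amplitude``."""
    sigma_px = corr_mm / pixel_size
    vec = np.stack(
        [ndimage.gaussian_filter(rng.standard_normal(shape), sigma_px) for _ in range(2)],
        axis=-1,
    )
    rms = np.sqrt(np.mean(np.sum(vec**2, axis=-1)))
    if rms > 0:
        vec *= amplitude / rms
    return vec


def make_phantom_volume(spec: PhantomSpec):
    """Build the clean multi-channel specimen.

    Returns ``(channels, mask, landmarks)`` where ``channels`` maps
    ``{"nissl", "myelin", "mr", "blockface"}`` to :class:`Volume3D` on a
    common grid.  The nissl-like channel carries the thin bright internal
    layer, the myelin-like channel the oblique rod and an internal tract,
    the mr-like channel a smooth composite; the blockface channel mixes
    the shared anatomy as an unstained photograph would.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.grid_shape)
    sp = spec.spacing
    x, y, z = np.meshgrid(
        *[np.arange(n, dtype=float) * sp for n in shape], indexing="ij"
    )
    c = spec.center_mm()
    dy = y - c[1]
    # sheared (body-following) coordinates
    xs = x - (c[0] + spec.shear[0] * dy)
    zs = z - (c[2] + spec.shear[1] * dy)
    r = np.sqrt(
        (xs / spec.radii[0]) ** 2 + (dy / spec.radii[1]) ** 2 + (zs / spec.radii[2]) ** 2
    )
    body = r <= 1.0
    # thin bright layer: Gaussian shell profile around layer_radius_frac
    shell_width = spec.layer_thickness / np.mean(spec.radii)
    shell = np.exp(-0.5 * ((r - spec.layer_radius_frac) / shell_width) ** 2) * body
    tract = np.exp(-0.5 * ((r - 0.45) / (1.5 * shell_width)) ** 2) * body
    # oblique rod
    p0, p1 = spec.rod_endpoints()
    d = p1 - p0
    pts = np.stack([x - p0[0], y - p0[1], z - p0[2]], axis=-1)
    t_par = np.clip(pts @ d / (d @ d), 0.0, 1.0)
    closest = t_par[..., None] * d
    dist = np.linalg.norm(pts - closest, axis=-1)
    rod = np.exp(-0.5 * (dist / (spec.rod_radius / 1.5)) ** 2)
    # smooth intra-tissue texture gives registration subvoxel signal
    texture = ndimage.gaussian_filter(rng.standard_normal(shape), 3.0)
    texture *= spec.texture_amplitude / max(texture.std(), 1e-12)

    # channels share the same anatomical structures (body, thin layer,
    # core) at the same locations with channel-specific contrast, as the
    # modalities of one specimen do; the tract and rod are myelin-specific
    core = np.exp(-0.5 * ((r - 0.0) / 0.3) ** 4) * body
    nissl = body * (0.55 + texture) + 0.40 * shell - 0.10 * core
    myelin = body * (0.45 + texture) + 0.55 * tract + 0.9 * rod * body
    mr = body * (0.60 + texture) + 0.20 * shell - 0.06 * core
    # blockface photographs show the frozen, unstained tissue at much
    # lower contrast than the stained sections, surrounded by the static
    # embedding block (cryogel edges, mold corners).  The block pattern
    # is fixed in camera coordinates — that is what propagation
    # alignment locks onto; the faint tissue is what the stained
    # sections register to.
    bf_tissue = ndimage.gaussian_filter(
        body * (0.35 + 0.6 * texture) + 0.18 * shell + 0.30 * rod * body, 1.2
    )
    pattern = _block_pattern((shape[0], shape[2]))
    blockface = np.maximum(bf_tissue, pattern[:, None, :])

    channels = {}
    for name, vals in (
        ("nissl", nissl),
        ("myelin", myelin),
        ("mr", mr),
        ("blockface", blockface),
        ("rod", rod * body),  # the bare banana-effect probe, for validation
    ):
        smoothed = ndimage.gaussian_filter(np.clip(vals, 0, None), 0.7)
        channels[name] = Volume3D(smoothed, sp)
    mask = Volume3D(body.astype(float), sp)

    landmarks = _sample_landmarks(rng, body, sp, spec.n_landmarks)
    return channels, mask, landmarks


def _block_pattern(shape2d) -> np.ndarray:
    """Static embedding-block features of a blockface photograph.

    A rectangular block edge plus asymmetric corner fiducials, fixed in
    camera coordinates across all sections.
    """
    nx, nz = shape2d
    pat = np.zeros((nx, nz))
    m = max(2, min(nx, nz) // 16)
    w = max(2, m // 2)
    pat[m : nx - m, m : m + w] = 0.8
    pat[m : nx - m, nz - m - w : nz - m] = 0.8
    pat[m : m + w, m : nz - m] = 0.8
    pat[nx - m - w : nx - m, m : nz - m] = 0.8
    xx, zz = np.meshgrid(np.arange(nx, dtype=float), np.arange(nz, dtype=float), indexing="ij")
    for (fx, fz, amp) in (
        (2.5 * m, 2.5 * m, 1.2),
        (nx - 2.5 * m, 3.2 * m, 1.0),
        (3.2 * m, nz - 2.5 * m, 0.8),
        (nx - 3.2 * m, nz - 2.5 * m, 1.1),
        (nx / 2.0, 2.0 * m, 0.9),
        (2.0 * m, nz / 2.0, 1.0),
    ):
        pat += amp * np.exp(-0.5 * (((xx - fx) ** 2 + (zz - fz) ** 2) / 2.0**2))
    return ndimage.gaussian_filter(pat, 0.7)


def _tissue_slab(body: np.ndarray) -> tuple:
    """First/last stack indices with enough tissue to cut a usable section."""
    areas = body.sum(axis=(0, 2))
    enough = areas >= max(40.0, 0.15 * areas.max())
    slab = np.flatnonzero(enough)
    return int(slab[0]), int(slab[-1])


def _sample_landmarks(rng, body, spacing, n):
    eroded = ndimage.binary_erosion(body, iterations=2)
    first, last = _tissue_slab(body)
    eroded[:, :first, :] = False
    eroded[:, last + 1 :, :] = False
    idx = np.argwhere(eroded)
    if len(idx) < n:
        idx = np.argwhere(body)
    sel = rng.choice(len(idx), size=n, replace=False)
    jitter = rng.uniform(-0.45, 0.45, size=(n, 3))
    coords = (idx[sel] + jitter) * spacing
    return LandmarkSet.from_points(coords)


def _random_rigid(rng, sigma_trans, sigma_rot_deg, center):
    t = rng.normal(0.0, sigma_trans, size=2)
    theta = np.radians(rng.normal(0.0, sigma_rot_deg))
    return RigidTransform2D(theta, t, center)


def section_phantom(spec: PhantomSpec):
    """Cut the phantom into a blockface series and stained series + truth.

    Returns ``(blockface, stained, truth)`` where ``stained`` maps stain
    channel names to :class:`SectionSeries`.  With ``interleave == 2``
    (the default) physical cuts alternate between the nissl-like and the
    myelin-like series, as when a specimen is collected into two
    alternating staining series; ``interleave == 1`` produces a single
    nissl-like series.

    Stained section ``i`` is the clean slice warped by its truth elastic
    field, moved by its truth rigid jitter and scaled by the drift
    factor.  Damaged sections get ``damaged_factor`` times the nominal
    elastic amplitude; they are recorded in the truth but their
    ``qc_flags`` are left unset — flagging is the pipeline's job.
    """
    channels, mask, landmarks = make_phantom_volume(spec)
    rng = np.random.default_rng(spec.seed + 1)
    sp = spec.spacing
    # only the tissue-bearing slab is cut: sections must contain enough
    # tissue for registration to be meaningful, as in a real specimen
    if spec.cut_full_range:
        offset, n_sections = 0, spec.grid_shape[1]
    else:
        offset, last = _tissue_slab(mask.values)
        n_sections = last - offset + 1
    section_shape = (spec.grid_shape[0], spec.grid_shape[2])
    center = (np.array(section_shape) - 1) / 2.0 * sp

    n_damaged = int(round(spec.damaged_fraction * n_sections))
    damaged = np.sort(rng.choice(n_sections, size=n_damaged, replace=False))
    damaged_set = set(int(i) for i in damaged)

    drift = np.exp(
        spec.drift_sigma
        * ndimage.gaussian_filter1d(rng.standard_normal(n_sections), 3.0, mode="reflect")
        / max(1e-12, _gf1d_std(3.0))
    )
    if spec.chatter:
        pattern = np.array([1.0, 0.0, -1.0])
        drift = drift * (1.0 + spec.chatter_amplitude * pattern[np.arange(n_sections) % 3])

    # smooth in-plane staining shrinkage: common to neighboring sections
    # (so neighbor-average refinement cannot remove it) but absent from
    # the reference volume — the 3D coregistration stage's job
    xg, zg = np.meshgrid(
        np.arange(section_shape[0], dtype=float) * sp,
        np.arange(section_shape[1], dtype=float) * sp,
        indexing="ij",
    )

    rigid, fields, bf_rigid = [], [], []
    blockface_secs, stained_all = [], []
    for i in range(n_sections):
        amp = spec.elastic_amplitude * (
            spec.damaged_factor if i in damaged_set else 1.0
        )
        vec = _smooth_noise_field(rng, section_shape, sp, amp, spec.elastic_corr)
        if spec.shrink_factor != 1.0 or spec.shrink_mod != 0.0:
            s_i = spec.shrink_factor + spec.shrink_mod * np.sin(
                2 * np.pi * i / max(n_sections, 1)
            )
            c2d = spec.body_center_at((offset + i) * sp)
            factor = 1.0 / s_i - 1.0
            shrink_vec = np.stack(
                [(xg - c2d[0]) * factor, (zg - c2d[1]) * factor], axis=-1
            )
            u_shrink = DisplacementField(shrink_vec, np.array([sp, sp]))
            u_elastic = DisplacementField(vec, np.array([sp, sp]))
            u = compose_fields(u_elastic, u_shrink)
        else:
            u = DisplacementField(vec, np.array([sp, sp]))
        J = _random_rigid(rng, spec.jitter_sigma_trans, spec.jitter_sigma_rot, center.copy())
        B = _random_rigid(
            rng, spec.blockface_jitter_trans, spec.blockface_jitter_rot, center.copy()
        )
        fields.append(u)
        rigid.append(J)
        bf_rigid.append(B)
        bf_clean = channels["blockface"].values[:, offset + i, :]
        blockface_secs.append(apply_rigid_2d(bf_clean, B, sp))
        stained_all.append(i)

    blockface = SectionSeries(
        blockface_secs, pixel_size=sp, thickness=sp, interleave=1, parity=0
    )

    stains = STAIN_CHANNELS[: min(spec.interleave, len(STAIN_CHANNELS))]
    stained = {}
    for parity, stain in enumerate(stains):
        secs = []
        for j in range(parity, n_sections, spec.interleave):
            clean_slice = channels[stain].values[:, offset + j, :]
            warped = warp_with_field(clean_slice, fields[j])
            moved = apply_rigid_2d(warped, rigid[j], sp)
            secs.append(drift[j] * moved)
        stained[stain] = SectionSeries(
            secs,
            pixel_size=sp,
            thickness=sp,
            interleave=spec.interleave,
            parity=parity,
        )

    rod_centroids = _true_rod_centroids(spec, n_sections, offset)
    clean = dict(channels)
    clean["mask"] = mask
    truth = PhantomTruth(
        rigid=rigid,
        fields=fields,
        blockface_rigid=bf_rigid,
        damaged=damaged,
        drift=drift,
        clean=clean,
        landmarks=landmarks,
        rod_centroids=rod_centroids,
        section_offset=offset,
        seed=spec.seed,
    )
    return blockface, stained, truth


def _true_rod_centroids(spec: PhantomSpec, n_sections: int, offset: int = 0) -> np.ndarray:
    p0, p1 = spec.rod_endpoints()
    out = np.full((n_sections, 2), np.nan)
    y = (np.arange(n_sections) + offset) * spec.spacing
    denom = p1[1] - p0[1]
    t = (y - p0[1]) / denom
    inside = (t >= 0) & (t <= 1)
    out[inside, 0] = p0[0] + t[inside] * (p1[0] - p0[0])
    out[inside, 1] = p0[2] + t[inside] * (p1[2] - p0[2])
    return out


def _gf1d_std(sigma: float, n: int = 4001) -> float:
    """Std of gaussian_filter1d applied to unit white noise (normalizer)."""
    impulse = np.zeros(n)
    impulse[n // 2] = 1.0
    k = ndimage.gaussian_filter1d(impulse, sigma)
    return float(np.sqrt(np.sum(k**2)))
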