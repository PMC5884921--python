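# Methods

This note documents the models, conventions, parameter choices and
known limitations of `serialrecon`. Everything quantitative stated here
is computed by the test suite or by `scripts/acceptance.py`.

## Coordinate and transform conventions

Voxel indices are 0-based; voxel `i` maps to world coordinate
`origin + i · spacing` (mm). The world frame is right-handed with axes
ordered (ML, AP, DV); sections are cut coronally, i.e. perpendicular to
AP, and section images are indexed (ML, DV). Rigid and affine
transforms are *forward point maps* (they say where a physical point
moves); images are resampled through the inverse, so a feature at `p`
appears at `T(p)` after warping. Displacement fields are *pull-back*
resampling fields in mm on the fixed grid: warping samples the input at
`x + u(x)`. Moving landmarks "with the image" through a field therefore
requires the field's inverse, obtained per point by the fixed-point
iteration `x ← p − u(x)`; the same iteration inverts whole fields
(converging when displacement gradients stay below one, which the
smoothness constraints guarantee).

The rotation center of per-section rigid transforms defaults to the
physical image center — registration then optimizes nearly decoupled
parameters, and the coarse/fine merge can operate on (θ, tx, ty) as
scalars with one shared center convention. Interpolation is linear for
intensities, nearest for masks and labels; out-of-domain samples take a
declared background value (default 0). Pixel sizes stored in file
headers are authoritative.

## The synthetic sectioned specimen

The phantom stands in for a cryosectioned, stained specimen with a
blockface camera:

- **Geometry.** A smooth ellipsoidal body (distinct per-axis radii —
  a near-spherical specimen would make mask registration rotationally
  ill-posed) whose center drifts linearly along the stack axis
  (`shear`, default 0.25 mm ML and 0.10 mm DV per mm AP). A thin bright
  internal shell (80 µm, emulating thin cell layers), a deeper tract
  shell, and a rod of 0.1 mm radius running along the sheared body axis.
  The rod is the quantitative probe for the z-shift: its true tilt
  against the stack axis is known in closed form (≈ 15.1° at the
  default shear).
- **Channels.** Nissl-like, myelin-like, MR-like and blockface
  intensities share the same anatomical structures at the same
  locations with channel-specific contrast, as the modalities of one
  specimen do; the tract and rod are myelin-specific, and a bare rod
  channel is exposed for validation. Blockface photographs show the
  frozen tissue at low contrast surrounded by the static embedding
  block (edges and corner fiducials fixed in camera coordinates —
  which is exactly what propagation alignment locks onto, while the
  faint tissue is what stained sections register to).
- **Sectioning.** Only the tissue-bearing slab is cut (sections with at
  least 15% of the peak cross-section area); alternate cuts go to the
  nissl-like and myelin-like series (interleave 2). Stained section
  `i` = clean slice, warped by a per-section elastic field, composed
  with a smooth in-plane shrinkage, moved by rigid mounting jitter, and
  scaled by intensity drift.
- **Corruptions and defaults.** Mounting jitter σ = 0.2 mm translation
  and 2° rotation (a few voxels at 40 µm/voxel — plausible slide
  mounting scatter); blockface camera jitter an order of magnitude
  smaller (0.02 mm, 0.2°). Elastic fields are smoothed white-noise
  vector fields with 0.4 mm correlation length scaled to 0.05 mm RMS;
  damaged sections (10% by default) receive 5× that amplitude and are
  recorded in the truth but not flagged — flagging is the pipeline's
  job. Staining shrinkage is an in-plane contraction to 96% with a ±2%
  slow modulation along the stack: it is common to neighboring sections
  (so neighbor-average refinement cannot remove it) and absent from the
  reference volume (so the 3D coregistration must). Intensity drift is
  multiplicative (log-scale σ 0.15, smoothed along the stack) with a
  period-3 ±8% alternation emulating batch-staining chattering. All
  randomness flows through one seeded generator.
- **What the phantom does not emulate.** Tears, folds and topology
  changes; photorealistic histology texture; imaging physics (the
  MR-like channel is just a smooth contrast variant). Passing tests
  therefore show that the algorithms recover the modeled geometric and
  intensity corruptions at realistic magnitudes — not that they survive
  arbitrary real-world artifacts.

## Section preprocessing

Tissue masks threshold the median-filtered (5×5) image at 94.8% of its
filtered maximum and keep the largest connected component
(8-connectivity in 2D, 26 in 3D). The threshold side is explicit
(`tissue_is_dark`): scanned stained sections are dark-on-light, the
phantom is bright-on-dark.

Automatic QC ranks each section by its best rigid-alignment-compensated
foreground correlation with neighbors at distances one and two (a
damaged section is dissimilar to all of them; an intact one beside a
run of damaged sections still matches a clean neighbor two cuts away).
Sections are pre-smoothed by 1.5 px so that thin cell layers, which
decorrelate between neighboring sections for purely anatomical reasons,
do not drown the damage signal. A running-median baseline excluding the
section itself absorbs the gradual anatomy change toward the specimen
poles; the noise scale is estimated from the positive residuals
(damage only lowers the statistic) with an absolute floor of half a
percent of correlation, and sections with less than 40% of the peak
tissue area abstain — at the poles anatomy changes faster than any
damage signal. At z = 3 this recovers ≥ 80% of damaged sections
(pooled over phantoms) with no false flags on undistorted stacks.
Flagged sections are replaced by their nearest unflagged neighbor (ties
toward the lower index), and the replacement map is kept so landmark
bookkeeping can account for the swapped anatomy.

Histogram matching excludes the declared background value from all
histograms: near the specimen poles sections are mostly background, and
letting that mass into the CDFs drags tissue intensities to spurious
levels. Each section is monotonically remapped toward the
Gaussian-weighted (σ = 5 sections, 256 bins) neighborhood histogram;
the exact weighting scheme of published weighted-histogram-matching
variants is not reproduced — the binding properties are rank
preservation, identity on equal histograms, and drift reduction.

## Rigid reconstruction

Pairwise rigid registration is a multi-resolution (default 2–3 level)
derivative-free (Powell) search over (θ, tx, ty) maximizing global
normalized cross-correlation (optionally locally mean-subtracted with a
configurable kernel; SSD is available), initialized by phase
correlation at the coarsest level. The search is deliberately *local*:
rotation is confined to ±25° around the initialization, the phase-
correlation offset is discarded when implausibly large, and steps that
register sections against references (coarse step) bound the
translation to 0.8 mm — 4σ of the mounting jitter. Without that bound,
occasional tiny end sections latch onto blockface fiducials about 1 mm
away whose spurious correlation genuinely exceeds the true optimum;
bounded local search encodes the prior that mounting jitter has a known
scale. A failed pairwise registration propagates the identity with a
logged warning rather than aborting a long run.

The blockface stack is aligned by serial propagation of consecutive
pairwise transforms from a reference section (composition is exact by
construction: `A_i = A_{i−1} ∘ P_i`). The coarse series registers each
stained section to blockface cut `interleave·i + parity`; the fine
series registers each section to its already-aligned inner neighbor,
outward from a central section, on the median-filtered registration
channel.

**Merging.** `merge_coarse_fine` implements parameter-space addition of
the high-pass fine parameters to the coarse parameters, with angles
unwrapped. Two numerical choices matter:

- The Gaussian low-pass removes the least-squares linear trend first,
  smooths the residual with reflective boundaries, and restores the
  trend. A plain reflective Gaussian flattens linear parameter trends
  at the stack ends, leaking an end-bend into the high band that biases
  the reconstructed obliqueness upward by ~15–20% on the rod phantom.
  Constant profiles and σ → 0 still reproduce the input exactly.
- The pipeline driver (`coarse_to_fine_transforms`) band-splits *both*
  series — low band from coarse, high band from fine, same kernel
  (σ = 5 sections). The raw sum `coarse + highpass(fine)` would correct
  the per-section jitter twice, since both series contain it at high
  frequency, and re-inject jitter-scale noise into the reconstruction.
  `merge_coarse_fine` itself is kept verbatim so its exact limit cases
  hold.

On the rod phantom this preserves the true tilt to within 10% (typically
1–5%) while fine-only reconstruction removes over half of it (typically
> 85%) — the banana effect in its purest form.

## Deformable reconstruction

One stack iteration warps every section toward the unweighted mean of
its neighbors (radius 1 by default, one-sided at the ends), using a
greedy demons-style update on locally normalized intensities (the CC
kernel radius sets the normalization window; a variance floor keeps
flat background flat instead of amplifying interpolation ripples).
Updates are synchronous — all targets come from the previous iterate,
so the result is independent of the processing order — and fields are
accumulated by composition and applied once to the original rigid-space
sections, avoiding repeated resampling blur. The default schedule
mirrors the printed parameter ranges: early iterations use gradient
step 0.5 with CC kernel 16, late ones 0.15 with kernel 4; σ = 3 voxels
on the similarity gradient, σ = 1 voxel on the field. Exact
per-iteration production schedules are configurable YAML rather than
hard-coded. Two safeguards keep the stack dissimilarity score
`S = mean(1 − CC(I_i, I_{i+1}))` non-increasing (observed tolerance
well under 1e-3): the pairwise registration returns the best field seen
if its metric worsens five updates in a row, and a stack-level greedy
acceptance discards per-section updates that worsen the plain
correlation to the section's target. Typical runs reduce S by ~85–93%
and keep the negative-Jacobian pixel fraction at zero.

## Volume coregistration

The affine stage registers binary masks (lightly smoothed so the SSD
has usable gradients) with centroid initialization and a two-level
(half-resolution then full) Powell search over 6 rigid or 12 affine
parameters; rotations and scales act about the moving-mask centroid.
The deformable stage drives a single field by a weighted sum of demons
forces on locally normalized intensities (CC kernel 5 voxels), smoothed
masks (SSD), and per-label signed-distance maps clipped at ±0.5 mm —
the distance-map term plays the role of an expert point-set/guidance
term: it attracts labeled regions that the intensity channels cannot
see. Default weights are 1:1:1 (the phantom pipeline runs
intensity + mask). The update cap is 0.4 voxel, the gradient smoothing
3 voxels, and the field smoothing radius ramps linearly 0.1 → 0.05 mm
over 10 steps; a multi-term metric tracks progress and the best field
is returned if it stops improving. On a 64³ two-label phantom under a
known ~2-voxel smooth warp the mean endpoint error is ≈ 0.23 voxel.

`resolve_full_mapping` composes the whole chain — per-section rigid,
per-section reconstruction field, stack geometry, 3D affine,
coregistration field — into one object that maps original 2D section
points into reference world coordinates (fields inverted per point),
so landmarks can be pushed through exactly the transforms the images
received.

## Evaluation and stereotaxy

Landmark discrepancies are Euclidean distances between homologous
(name-matched) points, summarized by linear-interpolation percentiles
(p5, q1, median, q3, p95). On the end-to-end phantom the affine
coregistration leaves a median of ~2–3 voxels, dominated by the
interleave quantization (a landmark's stack coordinate snaps to its
section) plus residual per-section errors; the deformable stage lowers
the mean median by ~15% and the mean 95th centile strictly, across
seeds. With ~10% of sections damaged and replaced, landmarks in
replaced slots carry an irreducible one-section anatomy error that
dominates the extreme tail.

The stereotaxic frame takes bregma, lambda and the two interaural
points: AP runs from lambda to bregma, ML along the interaural
component orthogonal to AP, DV completes the right-handed triad; the
frame transform is the pure rotation, with reference origins (bregma,
lambda, or the interaural midpoint) applied at lookup, so inputs that
already satisfy the constraints yield the identity. The reported
inclination is the pitch between the bregma–lambda segment and its
horizontal projection; DV is signed, positive dorsal. Rod straightness
is a total-least-squares 3D line fit (tilt against the stack axis, and
the maximum orthogonal residual); the per-section rod track is
extracted with a per-slice threshold anchored on the brightest
connected component, which is robust to slice-to-slice intensity drift.

## Problem sizes and determinism

The shipped experiments run on 64³-scale phantoms (≈ 2.5 mm specimens
at 40 µm/voxel, 30–50 sections per stack), where every stage's behavior
— jitter recovery to < 0.1 voxel RMS, tilt preservation, monotone
refinement, the direction of the coregistration improvement — is
measurable in minutes on one CPU; the algorithms contain nothing
resolution-specific beyond these parameters. All randomness passes
through seeded generators; re-running any experiment with the same seed
reproduces deterministic outputs bit-identically.

## Known limitations

- Cross-modality rigid registration of very small sections (near the
  specimen poles) has an honest accuracy floor of roughly a voxel and
  a degree; the merge's band-splitting and the bounded search absorb
  this, but per-section coarse transforms should not be read as exact
  there.
- Propagation alignment accumulates pairwise bias as a random walk;
  with a feature-rich static block this stays below ~0.02 voxel per
  section, but a blockface stack without static features would drift.
- The auto-QC detector abstains on pole sections and cannot separate a
  smooth, nearly-rigid "damage" from mounting jitter; its recall is
  evaluated pooled over phantoms because a single ~35-section series
  quantizes recall coarsely.
- The deformable machinery is greedy and composed, not a time-
  parameterized diffeomorphic flow; invertibility is encouraged by
  smoothing and step caps (and verified empirically), not guaranteed.
- Markov-random-field refinement of tissue classifications and manual
  mask editing are out of scope; externally supplied masks are accepted
  instead.
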