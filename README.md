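# serialrecon

Serial-section histology produces stacks of thin (tens of micrometres)
stained tissue sections that must be reassembled into a coherent 3D
volume before they can be compared or fused with tomographic imaging
(MRI, micro-CT). Each mounted section is rigidly displaced by slide
mounting, elastically distorted by cutting and staining, and its
staining intensity drifts from slide to slide; worse, aligning sections
only to one another silently straightens genuinely oblique anatomy —
the *z-shift* or *banana effect*. `serialrecon` implements the full
blockface-referenced reconstruction pipeline used in small-animal brain
atlas building, for people building such atlases or validating
reconstruction methodology:

- **Section preprocessing** — tissue masking (median filter, fractional
  threshold, largest connected component), automatic flagging and
  nearest-neighbor replacement of distorted sections, slice-to-slice
  staining-intensity correction by Gaussian-weighted histogram
  matching, 3D unsharp masking, KMeans tissue classification.
- **Rigid reconstruction** — the blockface photograph stack (a
  spatially consistent reference taken before each cut) is realigned by
  serial propagation from a reference section; each stained section is
  registered to its blockface counterpart (*coarse* series) and
  sequentially to its aligned inner neighbor (*fine* series). The two
  series are merged by frequency splitting of the transform parameters
  (θ, tx, ty): with per-section profiles smoothed by a Gaussian of
  σ sections along the stack,

      merged_i = coarse_i + (fine_i − G_σ(fine)_i),      σ = 5 sections

  so the anatomy-true low band comes from the blockface and the
  section-to-section coherence from the neighbor alignment.
- **Deformable reconstruction** — every section is iteratively warped
  toward the average of its nearest neighbors with a greedy,
  local-cross-correlation-driven update (similarity gradient smoothed
  with σ = 3 voxels, displacement field with σ = 1 voxel, gradient step
  0.15–0.5, CC kernel 4 or 16 px), fields composed across iterations
  and applied once to the rigid-space sections.
- **Volume coregistration** — affine mask-to-mask registration under an
  SSD criterion, then a multi-term deformable registration driven by
  weighted forces on intensities (windowed CC, kernel 5 voxels), masks
  (SSD) and per-label signed-distance maps, with the field smoothing
  radius ramped 0.1 → 0.05 mm over 10 steps.
- **Evaluation and stereotaxy** — Euclidean landmark discrepancies
  summarized by order statistics (p5, quartiles, median, p95), total-
  least-squares rod-straightness measurement, and a stereotaxic frame
  built from bregma, lambda and the interaural line (bregma and lambda
  leveled and on the midline; AP positive anterior, ML positive right,
  DV positive dorsal).

Because no deposited specimen is needed, everything is validated on a
**synthetic sectioned phantom**: a multi-channel ellipsoidal specimen
with a thin bright internal layer, an oblique rod probe and a linearly
drifting (sheared) body axis is cut into interleaved stained series
plus a blockface stack, with per-section rigid jitter, smooth elastic
distortion, slow staining shrinkage, intensity drift with a period-3
"chattering" pattern and a configurable fraction of damaged sections —
and every corruption is recorded as ground truth.

## Worked example

Run the end-to-end phantom pipeline (generate → preprocess → rigid →
deformable → coregister → evaluate) at the default 64³ grid:

```python
from serialrecon.pipeline import run_pipeline

results = run_pipeline({"seed": 1}, out_dir="runs/demo")
sa, sd = results["stats_affine"], results["stats_deform"]
print(f"affine:     median {sa.median:.4f} mm, p95 {sa.p95:.4f} mm")
print(f"deformable: median {sd.median:.4f} mm, p95 {sd.p95:.4f} mm")
```

prints (seed 1):

```
affine:     median 0.1208 mm, p95 0.2928 mm
deformable: median 0.1094 mm, p95 0.3012 mm
```

i.e. on this phantom the affine coregistration leaves a median
landmark discrepancy of about 3 voxels (at 40 µm/voxel) and the
deformable stage tightens the median; across seeds the 95th centile
decreases as well. `runs/demo/` holds the reconstructed volume
(`recon.nii.gz`), the merged transform series, the coregistration
field, the landmark statistics (`stats.json`) and a JSON-lines stage
log.

The same pipeline is available from the shell:

```bash
serialrecon run --seed 1 --out runs/demo
serialrecon phantom make --seed 3 --out runs/phantom
serialrecon recon rigid --stained runs/phantom/stained_nissl \
    --blockface runs/phantom/blockface --out runs/rigid
serialrecon evaluate --a a.csv --b b.csv --out stats.json
serialrecon stereotax frame --landmarks skull.csv --out frame.json
```

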