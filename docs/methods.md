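# Methods

## Problem and model

During head-and-neck radiotherapy the gross tumor volumes — the primary
tumor (GTVp, label 1) and involved lymph nodes (GTVn, label 2) — shrink,
shift and change intensity. Re-contouring them on a mid-treatment
T2-weighted MRI is hard when done from the image alone, because many
normal structures are tumor-like in intensity; but the pre-treatment
delineation, registered into the mid-treatment frame, pins down where each
target can be. `hncascade` implements that idea as a coarse-to-fine
cascade of two identical residual 3D U-Nets:

1. **Coarse stage.** The mid-RT image is concatenated with prior channels
   chosen by the *input recipe*: nothing (`mid_only`), the dilated
   registered pre-RT mask (`premask_mid`), or the registered pre-RT image
   plus the dilated mask (`preimg_premask_mid`). The network predicts
   3-class scores on the full fixed grid.
2. **Crop.** A fixed-size box is centered on the union of the coarse
   prediction's bounding box and the dilated prior's bounding box
   (configurable to prior-only), translated to lie inside the grid. If the
   coarse prediction is empty the prior anchors the crop alone; if both
   are empty the crop falls back to the grid center.
3. **Fine stage.** The cropped coarse output and the cropped mid-RT image
   (two channels) are refined by the second network; the result is pasted
   back into a background-initialized full grid.

### Prior dilation

The pre-RT mask is dilated per class with an anisotropic ellipsoid of
semi-axes (6, 6, 3) voxels (≈3 mm clinical margin at (0.5, 0.5, 2) mm
spacing), so a tumor that shrank and shifted between timepoints stays
inside its dilated prior. A voxel reached by both classes keeps its
original label if it had one, otherwise it takes the class whose nearest
original-foreground voxel is closer in mm (tie → GTVn, since losing nodes
costs more aggregated Dice). The cohort *overlap ratio* audit measures,
per class, the fraction of mid-RT tumor voxels covered by the dilated
prior, excluding cases where the class is absent at mid-RT.

### Networks

Encoder stages (default widths 16, 32, 64, 128, 256) are residual units of
two 3×3×3 convolutions with batch normalization and PReLU; every stage
after the first downsamples with a stride-2 first convolution, and a
1×1×1 projection aligns the shortcut when shape changes. The decoder
mirrors the encoder with kernel-2 stride-2 transposed convolutions
(chosen over kernel-3 because it doubles resolution exactly with no
output-padding ambiguity), concatenates same-resolution encoder features,
and a final 1×1×1 convolution emits 3 class scores. Five stages imply
divisibility of all spatial dims by 16; the full-scale grid 336×336×160
and crop 256×256×96 satisfy this. The miniature profile
(widths (4, 8, 16), grid 48×48×32 at (1, 1, 2) mm, crop 40×40×28) is a
first-class configuration that trains on one CPU in a few minutes; the
40×40×28 crop is chosen so it can contain a whole dilated primary lesion
at that scale.

The network stack — reverse-mode autodiff over numpy arrays, conv /
transposed-conv / batch-norm / PReLU layers, AdamW and a cyclic
learning-rate schedule — is implemented inside the package
(`hncascade.nn`); every layer's gradient is finite-difference checked in
the test suite. With batch size 1 (this pipeline's regime) batch-norm
batch statistics are per-volume statistics, and using stale running
averages at inference made evaluation erratic; the layers therefore use
the same per-volume statistics in eval mode by default (running averages
are still tracked and checkpointed, and textbook behavior is a flag).

### Preprocessing

Intensities are clipped to the [0.5, 99.5] percentiles computed over the
registered pre-RT mask foreground (configurable to the nonzero image,
which is also the automatic fallback when the mask is empty), then the
whole image is z-scored (mean/SD over all voxels after clipping —
whole-image is the conventional reading where the alternative would be a
region-restricted z-score). Volumes are resampled onto the fixed network
grid concentric with the source extent: trilinear for images, nearest
neighbor for labels, with background fill strictly outside the source
voxels' physical extent (a voxel has extent — coordinates within half a
voxel of an edge center are inside).

### Training

Both stages are optimized end-to-end with DiceCE (soft multi-class Dice
over the tumor classes, smoothing 1e-5, plus voxel-wise cross-entropy).
The two stage losses are combined with epoch-linear weights: coarse
0.9 → 0.1, fine 0.1 → 0.9, summing to 1 at every epoch, so early epochs
stabilize the localizer and later epochs refine. The crop-box computation
is integer routing and carries no gradient; gradient *does* flow from the
fine loss into the coarse network because the fine stage's coarse-output
channel is by default the soft class expectation Σ_c c·p_c, which equals
the integer label map wherever the prediction is confident. Hard integer
labels and one-hot encodings are config options (they sever that path and
correspond to the literal two-channel reading).

Optimizer: AdamW (decoupled weight decay 1e-2), batch size 1, triangular
cyclic learning rate. The full-scale recipe is 200 epochs at 3e-5; the
miniature profile uses 40 epochs with a single full cycle (ramp to 5e-3,
anneal back), which converged far more reliably at desk scale than
repeated short cycles. Augmentation (90° in-plane rotations, zoom
0.9–1.1, per-axis affine scaling ±0.1, gamma contrast 0.9–1.1, Gaussian
noise; probability 0.2 each, geometric transforms applied identically to
images and masks, intensity transforms to images only) is implemented and
tested but disabled in the miniature profile, whose phantom cohorts
already vary by construction.

Cohorts are split 80/10/10 into train/validation/test; k-fold
cross-validation rotates a single seeded permutation by i·n/k so the
held-out tenths differ per fold. (With three folds of 10 %+10 % held out,
not every case can appear in a held-out set; the rotation is the closest
consistent reading.) The best-validation checkpoint (mean aggregated Dice
over the tumor classes) is kept.

"Separate" training — the ablation the end-to-end claim is tested
against — trains the coarse network alone for half the epoch budget, then
freezes it and trains the fine network for the other half, so the
comparison is at equal total compute.

### Postprocessing

On predicted labels, in order: resolve GTVp/GTVn overlap (default keep
GTVn; nearest-component by mm distance as an option), remove per-class
connected components smaller than a voxel threshold, then bridge
same-class components whose exposed-face surface gap is within a mm
threshold by filling the shortest corridor (voxels whose summed distances
to the two components are within one voxel of the gap). Defaults —
26-connectivity, 50 voxels (≈25 mm³ at full scale; 4 voxels in the
miniature profile), 2 mm merge distance — are repository defaults, not
values from any dataset. The chain is idempotent on the fixtures tested;
pathological geometries where a bridge brings a third component within
merge distance could in principle require a second pass.

### Metrics

* **Aggregated Dice (DSCagg)** pools intersections and mask sizes over
  all cohort cases before the ratio; it is undefined (flagged, excluded)
  when a class is absent from the whole cohort.
* **Surface Dice at tolerance τ** discretizes each mask's surface as its
  exposed voxel faces (a face between a foreground voxel and a 6-neighbor
  background voxel or the volume edge), represented by the face center in
  mm with the face's physical area as weight; the score is the
  area-weighted fraction of each surface within τ of the other,
  symmetrized. τ defaults to 2 mm (the source of this pipeline never
  states the value it used; it is exposed as a flag). Comparisons use
  τ + 1e-9 to absorb float rounding at exact-tolerance distances. Both
  masks empty → 1.0; exactly one empty → 0.0.
* **HD95** is the max over both directions of the 95th percentile (linear
  interpolation) of nearest-neighbor distances between boundary-voxel
  centers in mm; undefined when either mask is empty.

All three agree with exhaustive brute-force oracles on randomized
anisotropic masks to 1e-9 mm in the test suite. Cohort summaries report
per-class values and their arithmetic mean; Python's round-half-even
makes 0.5625 print as 0.562 at three decimals.

## Synthetic phantoms

The generator emulates the statistical structure the method assumes, on a
48×48×32 grid at (1, 1, 2) mm by default:

* **Anatomy.** One GTVp (radii 5–9 mm) and 2–3 GTVn (radii 4–6.5 mm) as
  ellipsoids with smooth boundary perturbation, pairwise disjoint, with
  ≥10 mm between different classes (nodes are distinct structures away
  from the primary; the gap also exceeds twice the largest shift, which
  makes the dilated-prior coverage provable rather than approximate).
* **Longitudinal change.** The mid-RT lesion is a sub-level set of the
  same lesion field at threshold drawn from 0.6–1.0 (the outer shell
  regresses first), then shifted by an integer voxel offset within
  (±3, ±3, ±1); nodes vanish entirely with probability 0.1. Because the
  mid lesion is a shifted subset of the pre lesion and the shift lies
  inside the (6, 6, 3) dilation footprint, mid ⊆ dilated-prior holds
  exactly, per class — the idealized form of the high overlap ratios the
  margin is designed for. Swelling (threshold > 1) is configurable but
  off by default precisely because it breaks that exactness.
* **Intensity.** Background 100 with a smooth texture field (SD 10,
  correlation length 4 mm), lesions +10 (GTVp) / +12 (GTVn), voxel noise
  SD 6; the mid image is regenerated with fresh noise and a global
  multiplicative drift (SD 3 %). Crucially, 2–4 **confounder lesions** —
  ellipsoids with exactly a tumor class's intensity profile, present at
  both timepoints, absent from all masks, and kept ≥8 mm from true
  lesions so the dilated prior never reaches them — model the tumor-like
  normal structures (vessels, glands, benign nodes) that make
  intensity-only segmentation ambiguous. They are what the prior
  disambiguates: without them the image-only recipe can learn nodes from
  brightness alone and the ablation loses its contrast.

What the phantoms do **not** model: real head-and-neck anatomy,
deformable (non-affine) change between timepoints, registration error,
fat-suppression differences, MRI bias fields. Passing the phantom-scale
tests shows the machinery is correct and that the prior-conditioning
mechanism behaves as designed; it does not certify clinical performance.

## Problem sizes used by the tests and the acceptance script

Miniature cascades (widths 4/8/16) are trained for 40 epochs on 12
training phantoms (15-case cohort, 80/13/7 split) and evaluated on an
independent 12-case cohort; metric oracles run on 200 randomized mask
pairs up to 10×10×10 voxels; the coverage audit uses 50 cases. These
sizes were chosen so the entire suite runs on a single CPU in well under
half an hour while keeping the comparisons' margins wide. Typical
miniature results (seed 0): held-out DSCagg ≈ (0.45 GTVp, 0.52 GTVn) for
`premask_mid`, ≈ (0.11, 0.19) for `mid_only`, and end-to-end ≥ separate
(≈0.48 vs ≈0.39 mean). The ordering — prior-mask conditioning helps
decisively, joint training at least matches separate training, GTVn
scores above GTVp — mirrors the full-scale findings qualitatively;
absolute values at this scale are not comparable to full-scale ones.

## Known limitations

* The miniature learning rate (5e-3) and epoch count are tuned to the
  phantom task; the full-scale defaults (3e-5, 200 epochs) follow the
  published recipe but are not runnable here.
* Tiny networks on tiny cohorts have high run-to-run variance; the
  regression tests pin seeds and rely on margins, not on absolute scores.
* `merge_regions` computes pairwise component gaps exactly but bridges
  with a corridor heuristic; it never relabels classes and never
  decreases connectivity, which is what the contract requires.
* The checkpoint format stores raw arrays plus a JSON header; it is not
  interchangeable with other frameworks.
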