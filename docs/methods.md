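# Methods

## Problem and pipeline

The pituitary gland (PG) is a midline endocrine structure of under 10 mm
sitting at the base of the brain.  On a whole T1-weighted head volume
(256 x 256 x 192 voxels at 1 mm isotropic) it occupies a few hundred
voxels, which makes whole-volume segmentation networks both wasteful and
poorly conditioned.  `pituseg` implements the standard small-structure
recipe around that fact:

1. **Atlas ROI.**  The per-subject centroid of each training mask is the
   arithmetic mean of its foreground voxel indices; the cohort anchor is
   the per-axis mean of those centroids, rounded half-away-from-zero.  On
   a full-size grid this lands near voxel (128, 137, 131).  Training and
   inference are restricted to the 32^3 patch `[c - 16, c + 16)` per axis
   around that anchor; if the window would leave the volume, the center is
   shifted minimally to fit (so patches contain only real data), and the
   shift is reported.  A voxel-wise probability map (fraction of cohort
   masks labelling each voxel) documents how concentrated the structure is.
2. **Augmentation.**  Each training pair is expanded with random affine
   (rotation up to +-10 degrees per axis, isotropic scale +-10%,
   translation up to +-3 voxels) followed by random elastic deformation
   (uniform control-point displacements up to 2 voxels on an 8-voxel grid,
   cubic-interpolated to a dense field).  Images are resampled linearly,
   masks nearest-neighbour, with the identical sampled transform for both,
   so masks stay strictly binary.  Augmentation is applied inside each
   cross-validation fold to the training subjects only; copies never cross
   fold boundaries.  For efficiency the transforms act on a context patch
   (ROI + 8-voxel margin) rather than the whole head; the margin lets
   translations and rotations pull real tissue, not zeros, into the final
   central crop.
3. **Network.**  A 3D U-Net on single-channel cubic patches: `depth`
   encoder levels (default 3) of two 3x3x3 convolutions + instance norm +
   ReLU, 2x max-pooling between levels, channel widths doubling from
   `base_filters`, transposed-convolution upsampling with skip
   concatenation, and a final 1x1x1 convolution + sigmoid.  No
   deep-learning framework is a dependency: the forward and backward
   passes (convolution, pooling, instance norm, transposed convolution,
   Adam) are written directly in numpy with the hot loop arranged as BLAS
   matrix products, and are verified against central finite differences in
   the test suite.  Training is bit-reproducible given a seed.
4. **Loss and training.**  Soft-DICE loss
   `1 - (2*sum(p t) + eps) / (sum p + sum t + eps)` with `eps = 1`
   (avoids 0/0 on empty targets), computed per sample and averaged over
   the batch.  Optimizer Adam at initial learning rate 0.001, batch 16,
   up to 50 epochs, five-fold subject-level cross-validation.  Per-fold
   metrics (loss, IoU, DICE on the held-out fold) are computed after each
   epoch and reported as epoch averages; the selected checkpoint is the
   final-epoch model of the fold with the lowest averaged loss (ties by
   highest averaged DICE).
5. **Evaluation.**  Voxel-wise DICE, IoU, confusion counts, accuracy,
   precision, recall and F1 inside the 32^3 patch (on the full grid the
   background would pin accuracy near 1 regardless of quality), plus a
   subject-averaged ROC: per-subject curves from voxel probabilities,
   true-positive rates vertically averaged on a common 201-point
   false-positive-rate grid, area by trapezoid.
6. **Morphometry and statistics.**  From a binary mask: whole-gland volume
   (foreground count x voxel volume, mm^3) and mid-sagittal area
   (foreground count in the sagittal slice through the mask's own
   left-right centroid x in-plane voxel area, mm^2).  Subjects whose
   brain size (voxels above Otsu's threshold) falls outside
   `[Q1 - 1.5 IQR, Q3 + 1.5 IQR]` are excluded; the remaining cohort gets
   a Welch two-sample sex comparison and an OLS fit of
   `outcome ~ intercept + age + sex` (sex coded 1 = male), via statsmodels.

## Design choices in the open

- **Class imbalance at initialization.**  The output-layer bias starts at
  -2 so the initial foreground probability is ~0.12 rather than 0.5.
  With a target occupying <1% of the patch, a half-on start makes the
  soft-DICE denominator (and hence the gradient scale) be set by the
  32768-voxel background instead of the ~250-voxel target, and training
  stalls for many epochs.
- **Random-crop training.**  By default in the end-to-end pipeline the
  estimator trains on random 16^3 sub-crops of the 32^3 patches
  (`crop_size=16`), then fine-tunes for 5 epochs on the full patches
  (`finetune_full_epochs=5`).  The network is fully convolutional, so
  inference always runs on the full patch.  Crops raise the foreground
  fraction ~8x (better-conditioned DICE gradients), act as positional
  augmentation, and cut per-step cost 8x; the full-patch fine-tune aligns
  the final loss with the inference field of view.  Setting
  `crop_size=None` recovers plain full-patch training.
- **Orientation.**  All NIfTI images are reoriented to the closest
  canonical RAS+ axes on load; voxel coordinates (atlas center, slice
  indices) refer to this canonical array.  Axis 0 is left-right, which is
  what "sagittal slice" means here.
- **Mid-sagittal plane.**  The sagittal slice through the gland's own
  x-centroid, not the image midline: robust to head-position offsets, and
  the two nearly coincide for a midline structure.  The slice index used
  is recorded per subject.
- **Empty-vs-empty overlap.**  DICE and IoU are defined as 1.0 when both
  masks are empty (correct absence); 0/0 classification ratios are
  reported as 0 with an explicit flag.
- **Mask binarization** at >0.5 on load absorbs 0/255 label-map dialects.

## The phantom generator

Real cohort data is not bundled; every stage is exercised on synthetic
head phantoms.  A phantom is a bright head ellipsoid (intensity 100) on a
dark background with a small hyperintense gland-like ellipsoid (contrast
+80, mean semi-axes (5, 4, 3) voxels) near the scaled atlas position, plus
additive Gaussian noise (sd 5).  Ellipsoids are voxelized by fractional
occupancy (3^3 sub-voxel sampling, majority rule), keeping digitized
volumes within a few percent of (4/3) pi a b c.  The default grid is
64^3 at 1 mm — the full 256 x 256 x 192 grid is available by
configuration — with the atlas center scaled proportionally to
(32, 34.25, 32.75).

Cohorts draw ages uniformly from 21-68 years, fix the sex split at
11 male / 18 female for n = 29 (scaled proportionally otherwise), and set
each subject's target gland volume to

    volume = 280 - 0.46 * age - 30 * [male] + N(0, 10)   [mm^3]

realized by isotropically rescaling the jittered semi-axes.  The -0.46
mm^3/year age slope and the negative male offset give the regression
stage a known truth of the magnitude the method is meant to detect; the
noise level puts a 28-subject cohort's age effect at roughly the p ~ 0.003
significance scale, so single-cohort fits are informative but not
trivially significant.  Head semi-axes get bounded uniform +-10% linear
jitter — bounded so that the IQR fences of a normal cohort never flag a
regular head, while the optional planted outlier (3x head volume)
always lands far outside them.  Gland centers are jittered with sd
1 voxel and shapes with 5% per-axis sd.

What the phantoms do **not** emulate: anatomical shape, partial-volume
and Rician noise characteristics, bias fields, neighbouring bright
structures (fat, vessels), or inter-rater labelling noise.  Passing the
phantom suite therefore demonstrates that the pipeline's machinery —
geometry, training dynamics, metric arithmetic, statistics — is correct,
not that the trained weights would transfer to clinical MRI.

## Scaled-down end-to-end study

The end-to-end study simulates 40 subjects on the 64^3 grid (30 for
five-fold cross-validated training, 10 held out; one planted brain-size
outlier), trains the depth-3, 8-filter U-Net for 35 crop epochs + 5
full-patch epochs (batch 16, initial learning rate 0.001), evaluates the
selected checkpoint on the held-out subjects, and runs morphometry +
regression on the predicted masks of the whole cohort.  These problem
sizes are the package's desk-scale defaults; they complete in roughly a
quarter hour on a single CPU core.  Numbers this run produces
(held-out DICE/IoU/accuracy/ROC area, the recovered age-slope sign, the
exclusion count) are computed fresh each time by
`scripts/acceptance.py` and by the test suite.

## Numerical notes

- Per-patch z-scoring before the network; constant patches map to zeros.
- Probabilities accumulate in float32 through the network; losses and
  metrics are computed in float64.
- Max-pool gradients are split equally across tied maxima, keeping
  backprop deterministic.
- Quartiles for the IQR rule use linear interpolation (numpy default);
  the exclusion bounds are closed, so an all-equal sample excludes
  nothing.
- Centroid rounding is half-away-from-zero, applied per axis.

## Known limitations

- The numpy network targets 32^3 patches on CPU; it is not a
  general-purpose deep-learning stack (no GPU, kernels fixed at 3^3/1^3,
  stride-2 pooling only).
- Sub-voxel morphometry (surface-based area/volume) is out of scope; all
  measures are voxel counts times voxel size.
- The regression stage models age linearly; known inverted-U lifetime
  trajectories of gland volume are outside the emulated age range's
  model.
- Units follow the mask spacing (mm); printed coefficient magnitudes are
  only comparable across studies when the same units and mid-sagittal
  convention are used.
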