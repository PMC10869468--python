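# pituseg

Automated segmentation of the pituitary gland (PG) from T1-weighted brain
MRI, with the downstream morphometry and statistics that make the
segmentation useful: mid-sagittal area, whole-gland volume, and
sex-adjusted linear regression of both on age.

The PG is a midline endocrine structure of under 10 mm whose volume and
cross-sectional area shift with age, sex and endocrine disease, so a
reliable automated segmentation turns routine anatomical MRI into a
morphometric biomarker.  Manual delineation is slow and rater-dependent;
whole-volume networks waste memory on a structure occupying <0.01% of the
head.  `pituseg` instead trains a small 3D U-Net on a fixed 32^3 patch
anchored at the cohort-average gland centroid (near voxel (128, 137, 131)
on a 256 x 256 x 192, 1 mm grid), with affine + elastic augmentation and
five-fold cross-validation.

The core pieces, in the field's usual notation:

- **Soft-DICE loss** on predicted probabilities p against the binary mask t:
  `L = 1 - (2 Σ p t + ε) / (Σ p + Σ t + ε)`, ε = 1.
- **Overlap scores** DICE `2|A∩B| / (|A|+|B|)` and IoU `|A∩B| / |A∪B|`
  (D = 2J/(1+J)); voxel-wise confusion-matrix metrics and a
  subject-averaged ROC curve.
- **Morphometrics** from a mask with spacing (sx, sy, sz):
  total volume = N_fg · sx sy sz (mm^3); mid-sagittal area = foreground
  count in the sagittal slice through the mask's x-centroid · sy sz (mm^2).
- **Cohort model** `outcome ~ β0 + β_age · age + β_sex · 1[male]` by OLS,
  after excluding brain-size outliers by the 1.5 · IQR rule.

No imaging cohort is bundled; a phantom generator produces synthetic
heads (bright head ellipsoid, hyperintense gland-like target, Gaussian
noise) with covariates that drive gland volume through a known linear
age/sex model, so the whole pipeline runs and is tested end to end
offline.  The network itself is implemented in numpy (forward and
backward passes, Adam), so the package has no deep-learning framework
dependency and trains the patch-sized model on a plain CPU.

## Worked example

Python API — simulate a small cohort, cross-validate, evaluate:

```python
from pituseg.pipeline import run_phantom_study

study = run_phantom_study(seed=0)
rep = study["test_report"]
print("test averaged:", {k: round(v, 4) for k, v in rep.averaged.items()})
print("roc area:", round(rep.roc_area, 4))
reg = study["regression"]["total_volume_mm3"]
print("age coef:", round(reg.coefficients["age"], 4),
      "p:", round(reg.p_values["age"], 5))
print("excluded:", study["excluded_subjects"])
```

prints (seed 0, ~12 minutes on one CPU core):

```
test averaged: {'dice': 0.8737, 'iou': 0.7759, 'tp': 248.3, 'fp': 71.3, 'fn': 0.1, 'tn': 32448.3, 'accuracy': 0.9978, 'precision': 0.7762, 'recall': 0.9996, 'f1': 0.8737}
roc area: 0.9997
age coef: -0.3257 p: 0.00787
excluded: ['sub-035']
```

Reading the numbers: the selected cross-validated model overlaps the true
gland masks of the ten held-out phantoms at DICE 0.87 inside the 32^3
evaluation patch; the subject-averaged ROC area is near 1; the
sex-adjusted regression on the predicted masks of the 39 retained
subjects recovers a clearly negative age slope (generating slope
-0.46 mm^3/year), and the one subject planted with an abnormal (3x) head
volume is exactly the one the IQR rule excludes.

The same workflow is available as a CLI:

```bash
pituseg simulate --seed 0 --n 20 --out data/
pituseg train data/ --seed 0 --out run/
pituseg predict run/checkpoint.npz data/images/*.nii.gz --out pred/
pituseg evaluate run/checkpoint.npz data/ --out eval/
pituseg stats pred/morphometry.csv data/cohort.csv --out stats/
```

## Layout

| module | contents |
| --- | --- |
| `pituseg.volume_io` | NIfTI I/O, canonical RAS+ reorientation, grid checks |
| `pituseg.roi` | centroids, cohort probability map, 32^3 patch extract/insert |
| `pituseg.augment` | joint affine + elastic augmentation |
| `pituseg.nn` | numpy 3D conv-net core (layers, backprop, Adam) |
| `pituseg.model` | `UNet3DSegmenter` scikit-learn-style estimator, soft-DICE |
| `pituseg.training` | subject-level k-fold CV, fold metrics, checkpoint selection |
| `pituseg.evaluation` | DICE/IoU, confusion metrics, averaged ROC |
| `pituseg.morphometry` | mid-sagittal area, whole-gland volume |
| `pituseg.cohort_stats` | IQR exclusion, Welch comparison, OLS age regression |
| `pituseg.phantom` | synthetic heads + covariate cohorts |
| `pituseg.pipeline`, `pituseg.cli` | end-to-end study and `pituseg` CLI |

See `docs/methods.md` for the model, parameter defaults and their
rationale, what the phantoms do and do not emulate, and known limitations.
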