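"""Synthetic head phantoms with a known gland-like target.

Each phantom is a bright head ellipsoid on a dark background with a small
hyperintense midline ellipsoid standing in for the pituitary gland, plus
additive Gaussian noise.  The mask is the exact voxelization of the target
ellipsoid, so ground-truth morphometrics are known by construction.  A
cohort generator adds covariates (age, sex) that modulate the target volume
through a known linear model — volume = base + slope*age + offset*male —
so the downstream regression stage has a recoverable planted truth, and can
plant one abnormally large head to exercise the brain-size exclusion rule.

The default grid is 64^3 at 1 mm (the atlas center (128, 137, 131) of the
full 256x256x192 grid scales to (32, 34.25, 32.75)); the full-size grid
is available through the spec.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .morphometry import midsagittal_area, total_volume
from .volume_io import LabelMask, Volume

__all__ = ["PhantomSpec", "CohortSubject", "make_phantom", "make_cohort", "cohort_table"]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensity and cohort model of the synthetic heads.

    Cohort defaults mirror the regression cohort the pipeline targets:
    29 subjects, 11 male / 18 female, ages 21-68, a negative age slope of
    -0.46 mm^3 per year on gland volume, a smaller male gland, and one
    optional planted brain-size outlier.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    head_semiaxes: tuple[float, float, float] = (17.0, 18.0, 16.0)
    head_intensity: float = 100.0
    pg_center: tuple[float, float, float] = (32.0, 34.25, 32.75)
    pg_center_jitter_sd: float = 1.0
    pg_semiaxes: tuple[float, float, float] = (5.0, 4.0, 3.0)
    pg_shape_jitter_sd: float = 0.05
    pg_contrast: float = 80.0
    noise_sd: float = 5.0
    patch_size: int = 32
    # cohort covariate model
    n_subjects: int = 29
    n_male: int = 11
    age_range: tuple[float, float] = (21.0, 68.0)
    volume_base_mm3: float = 280.0
    volume_age_slope: float = -0.46
    volume_sex_offset: float = -30.0  # added for males
    volume_noise_sd: float = 10.0
    head_size_jitter: float = 0.10
    planted_outlier: bool = False
    outlier_head_volume_factor: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        half = self.patch_size // 2
        for c, n in zip(self.pg_center, self.shape):
            if c - half < -1 or c + half > n + 1:
                raise ValueError(
                    f"pg_center {self.pg_center} does not keep the {self.patch_size}^3 "
                    f"patch inside grid {self.shape}"
                )
        if self.n_male > self.n_subjects:
            raise ValueError("n_male exceeds n_subjects")


def _ellipsoid(shape, center, semiaxes, supersample: int = 3) -> np.ndarray:
    """Voxelize an ellipsoid by fractional occupancy.

    Each voxel is sampled on a ``supersample^3`` sub-grid and marked
    foreground when at least half the sample points fall inside; this keeps
    digitized volumes within a few percent of (4/3)pi*a*b*c even for
    semi-axes of only a few voxels, where a plain center-inside test
    undercounts markedly.
    """
    offs = (np.arange(supersample) + 0.5) / supersample - 0.5
    grids = np.ogrid[[slice(n) for n in shape]]
    acc = np.zeros(shape, dtype=np.uint16)
    for oz in offs:
        for oy in offs:
            for ox in offs:
                q = np.zeros(shape, dtype=np.float64)
                for g, o, c, a in zip(grids, (oz, oy, ox), center, semiaxes):
                    q = q + ((g + o - c) / a) ** 2
                acc += q <= 1.0
    return acc >= (supersample**3 + 1) // 2


def _reference_volume(semiaxes, spacing) -> float:
    return 4.0 / 3.0 * math.pi * np.prod(semiaxes) * np.prod(spacing)


def make_phantom(
    spec: PhantomSpec,
    rng: np.random.Generator | int = 0,
    target_volume_mm3: float | None = None,
    head_scale: float = 1.0,
) -> tuple[Volume, LabelMask, dict]:
    """Render one phantom head and its exact target mask.

    Parameters
    ----------
    target_volume_mm3 : float, optional
        Desired analytic target volume; the mean semi-axes (after shape
        jitter) are rescaled isotropically to hit it.  Defaults to the
        analytic volume of ``spec.pg_semiaxes``.
    head_scale : float
        Linear scale on the head semi-axes (used for the planted outlier).

    Returns ``(volume, mask, truth)`` where ``truth`` carries the exact
    voxel-counted morphometrics of the generated mask.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    center = np.asarray(spec.pg_center, dtype=float) + rng.normal(
        0.0, spec.pg_center_jitter_sd, 3
    )
    semi = np.asarray(spec.pg_semiaxes, dtype=float) * (
        1.0 + rng.normal(0.0, spec.pg_shape_jitter_sd, 3)
    )
    if target_volume_mm3 is not None:
        if target_volume_mm3 <= 0:
            raise ValueError(f"infeasible target volume {target_volume_mm3} mm^3")
        semi *= (target_volume_mm3 / _reference_volume(semi, spec.spacing)) ** (1.0 / 3.0)
    head_center = (np.asarray(spec.shape, dtype=float) - 1) / 2.0
    head = _ellipsoid(spec.shape, head_center, np.asarray(spec.head_semiaxes) * head_scale)
    pg = _ellipsoid(spec.shape, center, semi)
    if not pg.any():
        raise ValueError("generated gland mask is empty; spec semi-axes too small")
    if (pg & ~head).any():
        raise ValueError("gland ellipsoid is not fully inside the head ellipsoid")
    img = np.where(head, spec.head_intensity, 0.0) + np.where(pg, spec.pg_contrast, 0.0)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, spec.shape)
    vol = Volume(data=img.astype(np.float32), spacing=spec.spacing)
    mask = LabelMask(data=pg.astype(np.uint8), spacing=spec.spacing)
    area, slice_idx = midsagittal_area(mask)
    truth = {
        "total_volume_mm3": total_volume(mask),
        "midsagittal_area_mm2": area,
        "midsagittal_slice_index": slice_idx,
        "foreground_voxels": int(mask.data.sum()),
        "head_voxels": int(head.sum()),
    }
    return vol, mask, truth


@dataclass
class CohortSubject:
    subject_id: str
    age: float
    sex: str
    target_volume_mm3: float
    brain_size: int
    is_outlier: bool
    volume: Volume | None = None
    mask: LabelMask | None = None
    truth: dict = field(default_factory=dict)


def make_cohort(spec: PhantomSpec, render: bool = True) -> list[CohortSubject]:
    """Generate a covariate-driven phantom cohort; pure function of the spec.

    Ages are uniform over ``age_range``; sexes hit the requested counts
    exactly; each subject's target gland volume follows the linear
    age/sex model with Gaussian noise.  With ``render=False`` only the
    covariates and analytic brain sizes are produced (no images), which is
    what pure statistics simulations need.
    """
    if spec.n_subjects < 2:
        raise ValueError("cohort needs at least 2 subjects")
    rng = np.random.default_rng(spec.seed)
    ages = rng.uniform(*spec.age_range, spec.n_subjects)
    sexes = np.array(["male"] * spec.n_male + ["female"] * (spec.n_subjects - spec.n_male))
    rng.shuffle(sexes)
    outlier_idx = int(rng.integers(spec.n_subjects)) if spec.planted_outlier else -1
    # bounded (uniform) head-size variation: the IQR fences of a uniform
    # sample lie outside its support, so normal heads are never flagged
    head_scales = rng.uniform(1.0 - spec.head_size_jitter, 1.0 + spec.head_size_jitter,
                              spec.n_subjects)
    head_ref_voxels = int(_ellipsoid(spec.shape, (np.asarray(spec.shape) - 1) / 2.0,
                                     spec.head_semiaxes).sum())
    subjects = []
    for i in range(spec.n_subjects):
        target = (
            spec.volume_base_mm3
            + spec.volume_age_slope * ages[i]
            + (spec.volume_sex_offset if sexes[i] == "male" else 0.0)
            + rng.normal(0.0, spec.volume_noise_sd)
        )
        if target <= 0:
            raise ValueError(f"infeasible gland volume {target:.1f} mm^3 for subject {i}")
        head_scale = head_scales[i]
        if i == outlier_idx:
            head_scale = spec.outlier_head_volume_factor ** (1.0 / 3.0)
        subject = CohortSubject(
            subject_id=f"sub-{i:03d}",
            age=float(ages[i]),
            sex=str(sexes[i]),
            target_volume_mm3=float(target),
            brain_size=int(round(head_ref_voxels * head_scale**3)),
            is_outlier=i == outlier_idx,
        )
        if render:
            vol, mask, truth = make_phantom(
                spec, rng, target_volume_mm3=target, head_scale=head_scale
            )
            subject.volume, subject.mask, subject.truth = vol, mask, truth
            subject.brain_size = truth["head_voxels"]
        subjects.append(subject)
    return subjects


def cohort_table(subjects: list[CohortSubject], use_true_morphometry: bool = True) -> pd.DataFrame:
    """Covariate table (one row per subject) for the statistics stage.

    With ``use_true_morphometry`` the ground-truth volumes/areas are used
    where rendered masks exist, falling back to the analytic target volume
    otherwise (covariates-only cohorts).
    """
    rows = []
    for s in subjects:
        row = {
            "subject_id": s.subject_id,
            "age": s.age,
            "sex": s.sex,
            "brain_size": s.brain_size,
            "is_outlier": s.is_outlier,
        }
        if use_true_morphometry and s.truth:
            row["total_volume_mm3"] = s.truth["total_volume_mm3"]
            row["midsagittal_area_mm2"] = s.truth["midsagittal_area_mm2"]
        else:
            row["total_volume_mm3"] = s.target_volume_mm3
        rows.append(row)
    return pd.DataFrame(rows)
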