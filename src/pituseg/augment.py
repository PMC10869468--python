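"""Joint affine + elastic augmentation of image/mask pairs.

Both transforms resample the image with linear interpolation and the mask
with nearest-neighbour so the mask stays strictly binary, and the *same*
sampled transform is applied to both members of a pair.  Augmentation is
meant for training folds only; keeping augmented copies of a subject inside
that subject's fold is the caller's responsibility (see
:func:`pituseg.training.cross_validate`, which enforces it).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .volume_io import LabelMask, Volume

__all__ = ["AugmentationParams", "random_affine", "random_elastic", "augment_dataset"]


@dataclass(frozen=True)
class AugmentationParams:
    """Transform magnitudes for training-set expansion.

    Defaults are deliberately conservative: augmented glands should show a
    slightly different shape, size and position without implausible
    distortion.

    Attributes
    ----------
    rotation_range : float
        Max rotation per axis, degrees; sampled uniformly in +-range.
    scale_range : float
        Max fractional isotropic scale deviation; uniform in 1 +- range.
    translation_range : float
        Max translation per axis, voxels.
    elastic_control_spacing : int
        Spacing of the elastic control-point grid, voxels.
    elastic_max_displacement : float
        Max control-point displacement, voxels.
    copies_per_subject : int
        Augmented copies generated per original pair.
    seed : int
        Base seed; the whole augmented dataset is a pure function of
        (inputs, params).
    """

    rotation_range: float = 10.0
    scale_range: float = 0.10
    translation_range: float = 3.0
    elastic_control_spacing: int = 8
    elastic_max_displacement: float = 2.0
    copies_per_subject: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "rotation_range",
            "scale_range",
            "translation_range",
            "elastic_max_displacement",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.copies_per_subject < 0:
            raise ValueError("copies_per_subject must be >= 0")
        if self.elastic_control_spacing < 1:
            raise ValueError("elastic_control_spacing must be >= 1")


def _check_pair(vol: Volume, mask: LabelMask) -> None:
    if not vol.same_grid(mask):
        raise ValueError(f"image grid {vol.shape} != mask grid {mask.shape}")


def _rotation_matrix(angles_deg: np.ndarray) -> np.ndarray:
    ax, ay, az = np.deg2rad(angles_deg)
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def affine_transform_pair(
    vol: Volume, mask: LabelMask, matrix: np.ndarray, translation: np.ndarray
) -> tuple[Volume, LabelMask]:
    """Apply a known voxel-space affine (about the volume center) to a pair."""
    center = (np.array(vol.shape) - 1) / 2.0
    inv = np.linalg.inv(matrix)
    # ndimage maps output coords to input coords: in = inv @ (out - c - t) + c
    offset = center - inv @ (center + translation)
    img = ndimage.affine_transform(vol.data, inv, offset=offset, order=1, mode="constant")
    msk = ndimage.affine_transform(
        mask.data, inv, offset=offset, order=0, mode="constant"
    ).astype(np.uint8)
    return (
        replace(vol, data=img.astype(vol.data.dtype, copy=False)),
        replace(mask, data=msk),
    )


def random_affine(
    pair: tuple[Volume, LabelMask],
    params: AugmentationParams,
    rng: np.random.Generator,
) -> tuple[Volume, LabelMask]:
    """Random rotation + isotropic scale + translation, identical for both.

    With all ranges zero the inputs are returned unchanged, bitwise.
    """
    vol, mask = pair
    _check_pair(vol, mask)
    angles = rng.uniform(-params.rotation_range, params.rotation_range, size=3)
    scale = rng.uniform(1 - params.scale_range, 1 + params.scale_range)
    translation = rng.uniform(-params.translation_range, params.translation_range, size=3)
    if (
        params.rotation_range == 0
        and params.scale_range == 0
        and params.translation_range == 0
    ):
        return vol, mask
    matrix = _rotation_matrix(angles) * scale
    return affine_transform_pair(vol, mask, matrix, translation)


def _displacement_field(
    shape: tuple[int, int, int], params: AugmentationParams, rng: np.random.Generator
) -> np.ndarray:
    """Smooth field from uniform control-point displacements, cubic-upsampled."""
    spacing = params.elastic_control_spacing
    ctrl_shape = tuple(max(2, int(np.ceil(n / spacing)) + 1) for n in shape)
    ctrl = rng.uniform(
        -params.elastic_max_displacement,
        params.elastic_max_displacement,
        size=(3, *ctrl_shape),
    )
    field = np.empty((3, *shape))
    for ax in range(3):
        # smooth across control points so the local strain (hence volume
        # distortion) stays mild even at the full displacement bound
        smooth = ndimage.gaussian_filter(ctrl[ax], sigma=1.0, mode="nearest")
        zoom = [n / c for n, c in zip(shape, ctrl_shape)]
        field[ax] = ndimage.zoom(smooth, zoom, order=3, mode="nearest", grid_mode=True)
    return field


def random_elastic(
    pair: tuple[Volume, LabelMask],
    params: AugmentationParams,
    rng: np.random.Generator,
) -> tuple[Volume, LabelMask]:
    """Random smooth elastic deformation, identical for image and mask.

    Control-point displacements are uniform in +-elastic_max_displacement on
    a grid of elastic_control_spacing voxels and cubic-interpolated to a
    dense field (interpolation may overshoot the bound marginally between
    control points).  Zero max displacement is the bitwise identity.
    """
    vol, mask = pair
    _check_pair(vol, mask)
    field = None
    if params.elastic_max_displacement > 0:
        field = _displacement_field(vol.shape, params, rng)
    if field is None:
        return vol, mask
    coords = np.mgrid[[slice(n) for n in vol.shape]].astype(np.float64)
    coords += field
    img = ndimage.map_coordinates(vol.data, coords, order=1, mode="constant")
    msk = ndimage.map_coordinates(mask.data, coords, order=0, mode="constant").astype(
        np.uint8
    )
    return replace(vol, data=img.astype(vol.data.dtype, copy=False)), replace(mask, data=msk)


def augment_dataset(
    pairs: list[tuple[Volume, LabelMask]], params: AugmentationParams
) -> list[tuple[Volume, LabelMask]]:
    """Expand a training set: originals plus ``copies_per_subject`` copies each.

    Each copy is an independent random affine followed by an independent
    random elastic deformation.  The output (length ``n * (1 + copies)``)
    is fully determined by ``params.seed``.
    """
    out = list(pairs)
    for i, pair in enumerate(pairs):
        for k in range(params.copies_per_subject):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=params.seed, spawn_key=(i, k))
            )
            out.append(random_elastic(random_affine(pair, params, rng), params, rng))
    return out
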