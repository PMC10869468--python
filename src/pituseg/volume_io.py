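"""NIfTI volume and label-mask I/O with canonical reorientation.

All images are reoriented to nibabel's closest-canonical (RAS+) axes on
load, so voxel coordinates such as the atlas patch center are comparable
across files regardless of how each file encodes its axes.  Axis 0 is the
left-right axis in this convention, which is what the mid-sagittal
morphometry relies on.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import nibabel as nib
import numpy as np

__all__ = ["Volume", "LabelMask", "load_volume", "load_mask", "save_volume", "save_mask"]

CANONICAL_TAG = "RAS"


@dataclass
class Volume:
    """A 3D scalar image on a regular grid.

    Attributes
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel intensities in arbitrary units.
    spacing : tuple of float
        Per-axis voxel size in mm; strictly positive.
    affine : ndarray, shape (4, 4)
        Voxel-to-world transform of the canonical array.
    orientation_tag : str
        Always ``"RAS"`` after loading.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None
    orientation_tag: str = CANONICAL_TAG

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        if self.affine is None:
            self.affine = np.diag(list(self.spacing) + [1.0])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def same_grid(self, other: "Volume | LabelMask") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and self.orientation_tag == other.orientation_tag
        )


@dataclass
class LabelMask(Volume):
    """A binary mask on the same grid as its paired :class:`Volume`."""

    def __post_init__(self) -> None:
        super().__post_init__()
        data = np.asarray(self.data)
        if not np.isin(np.unique(data), (0, 1)).all():
            raise ValueError("LabelMask values must be exactly 0 or 1")
        self.data = data.astype(np.uint8)

    @property
    def n_foreground(self) -> int:
        return int(self.data.sum())


def _load_canonical(path: str | os.PathLike) -> tuple[np.ndarray, tuple, np.ndarray]:
    if not os.path.exists(path):
        raise FileNotFoundError(f"NIfTI file not found: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # corrupt header, wrong magic, ...
        raise IOError(f"could not read NIfTI file {path}: {exc}") from exc
    img = nib.funcs.squeeze_image(img)
    if img.ndim != 3:
        raise ValueError(f"expected a 3D image, got {img.ndim}D in {path}")
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing, np.asarray(img.affine)


def load_volume(path: str | os.PathLike) -> Volume:
    """Load a NIfTI image and reorient it to the canonical RAS+ axes.

    Intensities are unchanged up to the axis permutation/flips of the
    reorientation.
    """
    data, spacing, affine = _load_canonical(path)
    return Volume(data=np.asarray(data, dtype=np.float32), spacing=spacing, affine=affine)


def load_mask(path: str | os.PathLike, reference: Volume | None = None) -> LabelMask:
    """Load a binary mask, binarizing at 0.5 to absorb 0/255 label dialects.

    Parameters
    ----------
    reference : Volume, optional
        If given, the mask grid must match the reference grid exactly.
    """
    data, spacing, affine = _load_canonical(path)
    binary = (np.asarray(data, dtype=np.float64) > 0.5).astype(np.uint8)
    mask = LabelMask(data=binary, spacing=spacing, affine=affine)
    if reference is not None and not reference.same_grid(mask):
        raise ValueError(
            f"mask grid {mask.shape}/{mask.spacing} does not match "
            f"reference grid {reference.shape}/{reference.spacing}"
        )
    return mask


def _save(vol: Volume, path: str | os.PathLike, dtype) -> None:
    parent = os.path.dirname(os.path.abspath(str(path)))
    if not os.path.isdir(parent):
        raise IOError(f"parent directory does not exist: {parent}")
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=dtype), vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def save_volume(vol: Volume, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI; ``load_volume`` round-trips it exactly."""
    _save(vol, path, np.float32)


def save_mask(mask: LabelMask, path: str | os.PathLike) -> None:
    """Write a binary mask as uint8 NIfTI; round-trip safe."""
    _save(mask, path, np.uint8)
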