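"""Atlas-derived ROI: mask centroids, cohort probability map, patch extraction.

The segmentation network never sees a full head volume.  Training and
inference are constrained to a fixed cubic patch (default 32 voxels per
edge) anchored at the cohort-average centroid of the manually segmented
gland, which for the full 256x256x192 1 mm grid sits near voxel
(128, 137, 131).  The patch window is half-open, [c - size/2, c + size/2)
per axis, so the cube is exactly `size` wide with the center voxel at
local index size/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume_io import LabelMask, Volume

__all__ = [
    "PatchSpec",
    "ProbabilityMap",
    "mask_centroid",
    "cohort_center",
    "probability_map",
    "extract_patch",
    "insert_patch",
]


@dataclass(frozen=True)
class PatchSpec:
    """A fixed-size cubic region anchored at atlas voxel coordinates."""

    center: tuple[int, int, int]
    size: int = 32

    def __post_init__(self) -> None:
        if self.size <= 0 or self.size % 2 != 0:
            raise ValueError(f"patch size must be a positive even integer, got {self.size}")
        object.__setattr__(self, "center", tuple(int(c) for c in self.center))

    def to_dict(self) -> dict:
        return {"center": list(self.center), "size": self.size}

    @classmethod
    def from_dict(cls, d: dict) -> "PatchSpec":
        return cls(center=tuple(d["center"]), size=int(d["size"]))


@dataclass
class ProbabilityMap:
    """Voxel-wise fraction of cohort masks labelling each voxel foreground."""

    data: np.ndarray
    n_subjects: int

    def __post_init__(self) -> None:
        if self.data.min() < 0 or self.data.max() > 1:
            raise ValueError("probability map values must lie in [0, 1]")


def mask_centroid(mask: LabelMask) -> tuple[float, float, float]:
    """Arithmetic mean of foreground voxel indices, per axis."""
    idx = np.nonzero(mask.data)
    if idx[0].size == 0:
        raise ValueError("cannot compute centroid of an empty mask")
    return tuple(float(ax.mean()) for ax in idx)


def _round_half_away(x: float) -> int:
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


def _check_common_grid(masks: list[LabelMask]) -> None:
    if not masks:
        raise ValueError("need at least one mask")
    for m in masks[1:]:
        if not masks[0].same_grid(m):
            raise ValueError(f"mask grids differ: {masks[0].shape} vs {m.shape}")


def cohort_center(masks: list[LabelMask]) -> tuple[int, int, int]:
    """Mean of per-subject centroids, rounded half-away-from-zero per axis.

    This is the atlas anchor for the training patch: averaging the gland
    centroid over the training cohort localizes the structure because its
    position varies little across heads.
    """
    _check_common_grid(masks)
    centroids = np.array([mask_centroid(m) for m in masks])
    return tuple(_round_half_away(c) for c in centroids.mean(axis=0))


def probability_map(masks: list[LabelMask]) -> ProbabilityMap:
    """Voxel-wise mean of binary cohort masks."""
    _check_common_grid(masks)
    acc = np.zeros(masks[0].shape, dtype=np.float64)
    for m in masks:
        acc += m.data
    return ProbabilityMap(data=acc / len(masks), n_subjects=len(masks))


def _window(spec: PatchSpec, shape: tuple[int, int, int]):
    """Per-axis (start, stop, shift) under the shift-to-fit boundary rule."""
    half = spec.size // 2
    out = []
    for c, n in zip(spec.center, shape):
        if spec.size > n:
            raise ValueError(f"patch size {spec.size} exceeds volume extent {n}")
        lo = c - half
        shift = 0
        if lo < 0:
            shift = -lo
        elif lo + spec.size > n:
            shift = n - (lo + spec.size)
        lo += shift
        out.append((lo, lo + spec.size, shift))
    return out


def extract_patch(
    vol: Volume | LabelMask | np.ndarray, spec: PatchSpec, return_shift: bool = False
):
    """Extract the cubic subarray over ``[c - size/2, c + size/2)`` per axis.

    If the window would leave the volume, the center is shifted minimally so
    the window fits (shift-to-fit: every patch contains only real data).
    With ``return_shift=True`` the applied per-axis shift is returned too.
    """
    data = vol.data if isinstance(vol, Volume) else np.asarray(vol)
    win = _window(spec, data.shape)
    patch = data[tuple(slice(lo, hi) for lo, hi, _ in win)].copy()
    if return_shift:
        return patch, tuple(s for _, _, s in win)
    return patch


def insert_patch(target: np.ndarray, patch: np.ndarray, spec: PatchSpec) -> np.ndarray:
    """Write a patch back into a full-size array at the spec's window.

    Uses the same shift-to-fit rule as :func:`extract_patch`, so
    extract/insert round-trip exactly.  Returns a copy; last writer wins
    on repeated inserts.
    """
    patch = np.asarray(patch)
    if patch.shape != (spec.size,) * 3:
        raise ValueError(f"patch shape {patch.shape} does not match spec size {spec.size}")
    out = np.array(target, copy=True)
    win = _window(spec, out.shape)
    out[tuple(slice(lo, hi) for lo, hi, _ in win)] = patch
    return out
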