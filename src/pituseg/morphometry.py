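"""Gland morphometry from binary masks: mid-sagittal area and total volume.

Physical units come from the mask's voxel spacing: volume is the foreground
count times the voxel volume (mm^3), and the mid-sagittal area is the
foreground count in the sagittal slice through the gland's own left-right
centroid times the in-slice voxel area (mm^2).  Using the gland's centroid
rather than the image midline keeps the measure robust to small
head-position offsets; the chosen slice index is recorded per subject.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, asdict

import numpy as np

from .roi import mask_centroid, _round_half_away
from .volume_io import LabelMask

__all__ = ["MorphometryRecord", "total_volume", "midsagittal_area", "morphometry_table"]


@dataclass
class MorphometryRecord:
    subject_id: str
    midsagittal_slice_index: int
    midsagittal_area_mm2: float
    total_volume_mm3: float
    total_volume_cm3: float
    foreground_voxels: int
    error: str | None = None


def total_volume(mask: LabelMask) -> float:
    """Whole-gland volume in mm^3: foreground count x voxel volume."""
    sx, sy, sz = mask.spacing
    return float(mask.data.sum()) * sx * sy * sz


def midsagittal_area(mask: LabelMask) -> tuple[float, int]:
    """Area (mm^2) of the sagittal slice through the mask's x-centroid.

    Axis 0 is left-right in the canonical orientation; the slice index is
    the rounded x-centroid of the mask itself.
    """
    cx, _, _ = mask_centroid(mask)  # raises on empty mask
    idx = _round_half_away(cx)
    idx = min(max(idx, 0), mask.shape[0] - 1)
    _, sy, sz = mask.spacing
    area = float(mask.data[idx].sum()) * sy * sz
    return area, idx


def morphometry_table(masks: list[tuple[str, LabelMask]]) -> list[MorphometryRecord]:
    """One record per subject; per-subject failures are recorded, not fatal."""
    records = []
    for subject_id, mask in masks:
        try:
            vol = total_volume(mask)
            if mask.data.sum() == 0:
                records.append(
                    MorphometryRecord(subject_id, -1, 0.0, 0.0, 0.0, 0, error="empty mask")
                )
                continue
            area, idx = midsagittal_area(mask)
            records.append(
                MorphometryRecord(
                    subject_id=str(subject_id),
                    midsagittal_slice_index=idx,
                    midsagittal_area_mm2=area,
                    total_volume_mm3=vol,
                    total_volume_cm3=vol / 1000.0,
                    foreground_voxels=int(mask.data.sum()),
                )
            )
        except Exception as exc:  # keep processing the rest of the cohort
            records.append(MorphometryRecord(str(subject_id), -1, 0.0, 0.0, 0.0, 0, error=str(exc)))
    return records


def write_morphometry_csv(records: list[MorphometryRecord], path) -> None:
    fields = [
        "subject_id",
        "midsagittal_slice_index",
        "midsagittal_area_mm2",
        "total_volume_mm3",
        "total_volume_cm3",
        "foreground_voxels",
        "error",
    ]
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields)
        writer.writeheader()
        for rec in records:
            writer.writerow(asdict(rec))
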