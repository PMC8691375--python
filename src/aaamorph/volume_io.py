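"""Reading, writing and validation of binary aortic segmentation volumes.

The in-memory container is :class:`VoxelVolume`: a 3D boolean mask in a fixed
anatomical index order -- axis 0 = axial slice (cranio-caudal), axis 1 =
anteroposterior, axis 2 = lateral -- together with the voxel spacing in mm.
NIfTI images are reoriented into this convention on read so that downstream
measurements (anteroposterior diameter per axial slice) are taken in a
well-defined anatomical frame.

Tabular cohort data (one row per patient: baseline geometric features,
scan interval, annualized growth and growth category) round-trip through a
plain CSV schema.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

if TYPE_CHECKING:  # avoid a circular import; GrowthRecord lives in growth_analysis
    from .growth_analysis import GrowthRecord

log = logging.getLogger(__name__)

#: Column order of the cohort/feature CSV schema.
FEATURE_COLUMNS = [
    "patient_id",
    "apd_baseline_mm",
    "ui_baseline",
    "min_rc_baseline_mm",
    "days_between",
    "annual_growth_mm_yr",
    "category",
]

# 26-connectivity structuring element for component analysis.
_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


class EmptySegmentationError(ValueError):
    """Raised when a mask contains no foreground voxels."""


@dataclass
class VoxelVolume:
    """A binary segmentation on an anisotropic voxel grid.

    Parameters
    ----------
    mask:
        3D boolean array, index order (axial, anteroposterior, lateral).
    spacing:
        mm per voxel along each of the three axes; strictly positive.
    origin:
        mm coordinate of the center of voxel (0, 0, 0).
    """

    mask: np.ndarray
    spacing: tuple[float, float, float]
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError(f"mask must be 3D, got {self.mask.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3:
            raise ValueError("spacing must have 3 components")
        if not all(np.isfinite(s) and s > 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive and finite, got {self.spacing}")
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def n_foreground(self) -> int:
        return int(self.mask.sum())

    @property
    def n_axial_slices(self) -> int:
        """Number of axial slices containing at least one foreground voxel."""
        return int(self.mask.any(axis=(1, 2)).sum())

    def foreground_indices(self) -> np.ndarray:
        """(N, 3) integer voxel indices of foreground voxels."""
        return np.argwhere(self.mask)

    def foreground_mm(self) -> np.ndarray:
        """(N, 3) mm coordinates of foreground voxel centers."""
        return self.foreground_indices() * np.asarray(self.spacing) + self.origin


def validate_volume(volume: VoxelVolume) -> VoxelVolume:
    """Enforce the mask invariants, returning a cleaned copy.

    The mask must contain at least one foreground voxel.  If the foreground
    splits into several 26-connected components (speckle is common in
    clinical segmentations), only the largest is kept and a warning is
    logged.  Validation is idempotent.
    """
    if volume.n_foreground == 0:
        raise EmptySegmentationError("empty segmentation: no foreground voxels")
    labels, n_comp = ndimage.label(volume.mask, structure=_STRUCT_26)
    if n_comp == 1:
        return VoxelVolume(volume.mask, volume.spacing, volume.origin)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n_comp + 1))
    keep = int(np.argmax(sizes)) + 1
    dropped = int(sizes.sum() - sizes[keep - 1])
    log.warning(
        "segmentation has %d connected components; keeping largest "
        "(%d voxels), dropping %d voxels", n_comp, int(sizes[keep - 1]), dropped,
    )
    return VoxelVolume(labels == keep, volume.spacing, volume.origin)


@dataclass
class ScanMeta:
    """Identity and timing of one scan in a serial pair."""

    patient_id: str
    scan_day: int
    role: str  # "baseline" | "followup"

    def __post_init__(self) -> None:
        if self.role not in ("baseline", "followup"):
            raise ValueError(f"role must be 'baseline' or 'followup', got {self.role!r}")
        if self.scan_day < 0:
            raise ValueError("scan day index must be non-negative")


def read_mask(path: str | Path, threshold: float = 0.5) -> VoxelVolume:
    """Read a NIfTI segmentation into the anatomical index convention.

    Voxels with intensity strictly above ``threshold`` are foreground (the
    0.5 default binarizes probabilistic masks).  The image is reoriented to
    closest-canonical (RAS) and transposed so that axis 0 is axial
    (inferior->superior), axis 1 anteroposterior and axis 2 lateral.
    Validation is applied: the largest 26-connected component is retained.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.as_closest_canonical(nib.load(path))
    data = np.asanyarray(img.dataobj)
    affine = img.affine
    spacing_ras = np.sqrt((affine[:3, :3] ** 2).sum(axis=0))
    origin_ras = affine[:3, 3]
    # RAS axes are (lateral, AP, axial); reorder to (axial, AP, lateral).
    mask = np.transpose(data > threshold, (2, 1, 0))
    spacing = tuple(spacing_ras[[2, 1, 0]])
    origin = origin_ras[[2, 1, 0]]
    if not all(np.isfinite(s) and s > 0 for s in spacing):
        raise ValueError(f"non-positive voxel spacing in header: {spacing}")
    if not mask.any():
        raise EmptySegmentationError(
            f"empty segmentation: no voxel above threshold {threshold} in {path.name}"
        )
    return validate_volume(VoxelVolume(mask, spacing, origin))


def write_mask(volume: VoxelVolume, path: str | Path) -> None:
    """Write a VoxelVolume as a NIfTI image (RAS orientation, uint8 data)."""
    path = Path(path)
    data = np.transpose(volume.mask.astype(np.uint8), (2, 1, 0))
    affine = np.eye(4)
    sp = np.asarray(volume.spacing)[[2, 1, 0]]
    affine[:3, :3] = np.diag(sp)
    affine[:3, 3] = volume.origin[[2, 1, 0]]
    nib.save(nib.Nifti1Image(data, affine), str(path))


def write_features_table(records: Sequence["GrowthRecord"], path: str | Path) -> None:
    """Write growth records to CSV using the :data:`FEATURE_COLUMNS` schema."""
    from .growth_analysis import records_to_frame

    if len(records) == 0:
        raise ValueError("cannot write an empty record list")
    frame = records_to_frame(records)
    # %.17g guarantees float64 round-trips exactly through the text format
    frame.to_csv(path, index=False, float_format="%.17g")


def read_features_table(path: str | Path) -> list["GrowthRecord"]:
    """Read growth records from a CSV written by :func:`write_features_table`."""
    from .growth_analysis import frame_to_records

    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in FEATURE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"feature table {path} missing columns: {missing}")
    return frame_to_records(frame)
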