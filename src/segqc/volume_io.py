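"""Reading, writing and validation of 3D lung label volumes.

Label volumes are integer NIfTI-1 images with the convention
0 = background, 1 = right lung, 2 = left lung. On read, every volume is
reoriented to a canonical RAS-like axis order — array axis 0 runs left to
right (L→R), axis 1 posterior to anterior (P→A) and axis 2 inferior to
superior (I→S) — so that "axial" and "coronal" are unambiguous downstream.
Masks are categorical; affines that are not axis-aligned (sheared or
oblique grids) are rejected rather than resampled, because interpolating a
label map would corrupt it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np

VALID_LABELS = (0, 1, 2)
RIGHT_LUNG = 1
LEFT_LUNG = 2
#: array axis -> anatomical axis under the canonical orientation
CANONICAL_AXES = ("L-R", "P-A", "I-S")


class VolumeFormatError(ValueError):
    """The file is not an integer label volume we can ingest."""


class VolumeValidationError(ValueError):
    """The voxel data violates the label-volume contract."""


def _check_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise VolumeValidationError(f"spacing must be three positive floats, got {spacing}")
    return spacing


def _check_axis_order(axis_order) -> tuple[str, str, str]:
    axis_order = tuple(axis_order)
    if sorted(axis_order) != sorted(CANONICAL_AXES):
        raise VolumeValidationError(
            f"axis_order must be a permutation of {CANONICAL_AXES}, got {axis_order}"
        )
    return axis_order


@dataclass(eq=False)
class LabelVolume:
    """3D integer label array with voxel spacing and anatomical axis order.

    Attributes
    ----------
    voxels : ndarray of int, 3D
        Label codes, each in {0, 1, 2}.
    spacing : (sx, sy, sz)
        Voxel edge lengths in mm along the three array axes.
    axis_order : tuple of str
        Anatomical direction of each array axis, e.g. ``("L-R", "P-A", "I-S")``.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    axis_order: tuple[str, str, str] = CANONICAL_AXES

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise VolumeValidationError(f"expected a 3D array, got ndim={self.voxels.ndim}")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise VolumeFormatError(f"label voxels must be integers, got dtype {self.voxels.dtype}")
        bad = np.setdiff1d(np.unique(self.voxels), VALID_LABELS)
        if bad.size:
            raise VolumeValidationError(f"labels outside {set(VALID_LABELS)}: {bad.tolist()}")
        self.spacing = _check_spacing(self.spacing)
        self.axis_order = _check_axis_order(self.axis_order)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def affine(self) -> np.ndarray:
        """Diagonal RAS affine implied by the canonical orientation."""
        return np.diag([*self.spacing, 1.0])

    def with_voxels(self, voxels: np.ndarray) -> "LabelVolume":
        return replace(self, voxels=voxels)


@dataclass(eq=False)
class BinaryMask:
    """Boolean mask on the same grid as its source :class:`LabelVolume`."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    axis_order: tuple[str, str, str] = CANONICAL_AXES

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 3:
            raise VolumeValidationError(f"expected a 3D array, got ndim={self.voxels.ndim}")
        self.spacing = _check_spacing(self.spacing)
        self.axis_order = _check_axis_order(self.axis_order)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def with_voxels(self, voxels: np.ndarray) -> "BinaryMask":
        return replace(self, voxels=np.asarray(voxels, dtype=bool))


def _assert_axis_aligned(affine: np.ndarray, path) -> None:
    """Reject sheared/oblique grids: each world axis must align with one array axis."""
    rotation = np.asarray(affine)[:3, :3]
    norms = np.linalg.norm(rotation, axis=0)
    if np.any(norms == 0):
        raise VolumeFormatError(f"{path}: degenerate affine (zero-length axis)")
    cosines = np.abs(rotation / norms)
    # each column must be a signed unit vector along one world axis
    if not np.allclose(np.sort(cosines, axis=0)[:2], 0.0, atol=1e-3):
        raise VolumeFormatError(
            f"{path}: affine is sheared or oblique; label volumes are categorical "
            "and are not resampled — reorient the file to an axis-aligned grid first"
        )


def read_label_volume(path) -> LabelVolume:
    """Read a NIfTI-1 label volume, reorienting it to the canonical axis order.

    Raises
    ------
    VolumeFormatError
        If the data are not integer-valued or the grid is not axis-aligned.
    VolumeValidationError
        If labels outside {0, 1, 2} are present (the message lists them).
    """
    path = Path(path)
    img = nib.load(str(path))
    _assert_axis_aligned(img.affine, path)
    img = nib.as_closest_canonical(img)  # permutes/flips axes to RAS
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.round(data)
        if not np.allclose(data, rounded, atol=1e-6):
            raise VolumeFormatError(f"{path}: non-integer voxel values")
        data = rounded
    data = data.astype(np.int16)
    # header zooms are float32; round so e.g. 1.4 survives a round trip exactly
    spacing = tuple(round(float(z), 6) for z in img.header.get_zooms()[:3])
    return LabelVolume(voxels=data, spacing=spacing, axis_order=CANONICAL_AXES)


def write_label_volume(vol: LabelVolume, path) -> None:
    """Write a label volume as NIfTI-1 (.nii or .nii.gz by suffix)."""
    path = Path(path)
    img = nib.Nifti1Image(vol.voxels.astype(np.uint8), affine=vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def extract_binary_mask(vol: LabelVolume, label: int) -> BinaryMask:
    """Binary mask of one lung: true exactly where ``voxels == label``."""
    if label not in (RIGHT_LUNG, LEFT_LUNG):
        raise ValueError(f"label must be {RIGHT_LUNG} (right) or {LEFT_LUNG} (left), got {label}")
    return BinaryMask(
        voxels=vol.voxels == label, spacing=vol.spacing, axis_order=vol.axis_order
    )
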