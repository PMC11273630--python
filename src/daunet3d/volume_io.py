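"""NIfTI I/O for CT volumes and binary organ masks.

Internal axis convention is ``(depth, height, width)`` — slice axis first —
with per-axis physical spacing in millimetres.  NIfTI files store axes as
(x, y, z), so arrays are transposed on load and the original affine is kept
opaquely for round-tripping.  CT spacing is typically anisotropic (sub-mm
in-plane, up to several mm between slices) and every consumer of these types
is spacing-aware.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np


class VolumeFormatError(ValueError):
    """File content not usable as a scalar CT volume or a binary mask."""


def _default_affine(spacing: tuple[float, float, float]) -> np.ndarray:
    # (x, y, z) voxel sizes = (width, height, depth) spacing reversed
    return np.diag([spacing[2], spacing[1], spacing[0], 1.0])


@dataclass
class CTVolume:
    """A 3D scalar grid in Hounsfield units.

    ``voxels`` is (depth, height, width) float32; ``spacing`` is the
    (axial, row, col) voxel size in mm, all strictly positive; ``affine``
    carries NIfTI orientation metadata opaquely.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise VolumeFormatError(
                f"volume must be 3D, got shape {self.voxels.shape}")
        if not np.all(np.isfinite(self.voxels)):
            raise VolumeFormatError("volume contains non-finite voxels")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise VolumeFormatError(
                f"spacing must be 3 positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class SegmentationMask:
    """A binary grid aligned to a :class:`CTVolume`; foreground = organ."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        arr = np.asarray(self.voxels)
        if arr.ndim != 3:
            raise VolumeFormatError(f"mask must be 3D, got shape {arr.shape}")
        uniq = np.unique(arr)
        if not np.isin(uniq, (0, 1)).all():
            raise VolumeFormatError(
                f"mask values must be exactly 0 or 1, found {uniq[:10]}")
        self.voxels = arr.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise VolumeFormatError(
                f"spacing must be 3 positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def matches_grid(self, vol: "CTVolume") -> bool:
        return (self.shape == vol.shape
                and np.allclose(self.spacing, vol.spacing))


def _load(path) -> tuple[np.ndarray, tuple[float, float, float], np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeFormatError(
            f"{path}: expected a 3D scalar image, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    # file order (x, y, z) -> internal (depth, height, width) = (z, y, x)
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return data.T, spacing, img.affine


def read_volume(path) -> CTVolume:
    """Read a NIfTI CT scan as a (depth, height, width) float32 HU grid."""
    data, spacing, affine = _load(path)
    data = data.astype(np.float32)
    if not np.all(np.isfinite(data)):
        raise VolumeFormatError(f"{path}: volume contains non-finite voxels")
    return CTVolume(voxels=data, spacing=spacing, affine=affine)


def read_mask(path) -> SegmentationMask:
    """Read a NIfTI label image as a binary organ mask.

    Any label > 0 maps to foreground: on LiTS-style annotations the liver is
    label 1 and lesions inside it are label 2, and both count as liver for
    the single-organ task.
    """
    data, spacing, affine = _load(path)
    if np.issubdtype(data.dtype, np.floating):
        rounded = np.rint(data)
        if not np.allclose(data, rounded, atol=1e-6):
            raise VolumeFormatError(f"{path}: mask labels are not integers")
        data = rounded
    if data.min() < 0:
        raise VolumeFormatError(f"{path}: mask contains negative labels")
    return SegmentationMask(voxels=(data > 0).astype(np.uint8),
                            spacing=spacing, affine=affine)


def write_volume(vol_or_mask: CTVolume | SegmentationMask, path) -> Path:
    """Write a volume (float32) or mask (uint8) as NIfTI; round-trip safe."""
    path = Path(path)
    obj = vol_or_mask
    if isinstance(obj, SegmentationMask):
        data = obj.voxels.astype(np.uint8)
    elif isinstance(obj, CTVolume):
        data = obj.voxels.astype(np.float32)
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    affine = obj.affine if obj.affine is not None else _default_affine(obj.spacing)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(data.T, affine)  # back to file order (x, y, z)
    img.header.set_zooms((obj.spacing[2], obj.spacing[1], obj.spacing[0]))
    try:
        nib.save(img, str(path))
    except OSError as e:
        raise OSError(f"cannot write NIfTI to {path}: {e}") from e
    return path
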