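"""CT preprocessing and training-time augmentation.

The preprocessing recipe for abdominal CT: clamp intensities to a liver
window of [-200, 200] HU (suppressing bone and air extremes irrelevant to
the organ), optionally rescale the window to [0, 1] for the optimizer,
halve the in-plane resolution (512 -> 256), and resample the slice axis to
1 mm spacing.  Augmentation applies one random rigid+scale transform about
the axial axis to image and mask jointly, then a random crop.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .volume_io import CTVolume, SegmentationMask


@dataclass(frozen=True)
class PreprocessSpec:
    """Intensity window and target geometry.

    ``target_inplane``/``target_axial_spacing`` of None leave that axis
    untouched (useful when inputs are already on the target grid).
    """

    hu_window: tuple[float, float] = (-200.0, 200.0)
    target_inplane: tuple[int, int] | None = (256, 256)
    target_axial_spacing: float | None = 1.0
    normalize_to_unit: bool = True

    def __post_init__(self):
        low, high = self.hu_window
        if not low < high:
            raise ValueError(f"hu_window must satisfy low < high, got {self.hu_window}")
        if self.target_inplane is not None:
            if any(int(t) != t or t <= 0 for t in self.target_inplane):
                raise ValueError("target_inplane must be positive integers")
        if self.target_axial_spacing is not None and self.target_axial_spacing <= 0:
            raise ValueError("target_axial_spacing must be > 0")


@dataclass(frozen=True)
class AugmentSpec:
    """One random rotation (about the slice axis), isotropic in-plane scale,
    and random crop, all drawn from ``seed``."""

    rotation_max_deg: float = 15.0
    scale_range: tuple[float, float] = (0.9, 1.1)
    crop_shape: tuple[int, int, int] | None = None
    fill_value: float = -200.0  # out-of-field fill; the window minimum
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.scale_range
        if not (0 < lo <= hi):
            raise ValueError(f"scale_range must be 0 < min <= max, got {self.scale_range}")
        if self.rotation_max_deg < 0:
            raise ValueError("rotation_max_deg must be >= 0")


def clip_and_normalize(vol: CTVolume, spec: PreprocessSpec) -> CTVolume:
    """Clamp HU into the window; optionally map the window linearly to [0, 1].

    The clamp alone is idempotent; with ``normalize_to_unit`` the output
    lives on a different scale and is meant to be applied once, directly
    before the network.
    """
    low, high = spec.hu_window
    out = np.clip(vol.voxels, low, high)
    if spec.normalize_to_unit:
        out = (out - low) / (high - low)
    return CTVolume(voxels=out, spacing=vol.spacing, affine=vol.affine)


def resample(vol: CTVolume, mask: SegmentationMask | None,
             spec: PreprocessSpec) -> tuple[CTVolume, SegmentationMask | None]:
    """Resize in-plane to ``target_inplane`` and respace the slice axis.

    The image is interpolated trilinearly, the mask by nearest neighbour so
    it stays binary.  In-plane spacing scales by the resize factor (512 ->
    256 doubles it); axial spacing becomes ``target_axial_spacing`` exactly.
    """
    if mask is not None and not mask.matches_grid(vol):
        raise ValueError("mask grid does not match volume grid")
    d, h, w = vol.shape
    sp_d, sp_h, sp_w = vol.spacing

    new_h, new_w = (h, w) if spec.target_inplane is None else spec.target_inplane
    if spec.target_axial_spacing is None:
        new_d, new_sp_d = d, sp_d
    else:
        if d == 1 and not np.isclose(sp_d, spec.target_axial_spacing):
            raise ValueError("cannot respace the axial axis of a single-slice volume")
        new_d = max(1, int(round(d * sp_d / spec.target_axial_spacing)))
        new_sp_d = spec.target_axial_spacing

    factors = (new_d / d, new_h / h, new_w / w)
    new_spacing = (new_sp_d, sp_h * h / new_h, sp_w * w / new_w)

    if factors == (1.0, 1.0, 1.0):
        out_img = vol.voxels.copy()
    else:
        out_img = ndimage.zoom(vol.voxels, factors, order=1, mode="nearest")
    if out_img.shape != (new_d, new_h, new_w):  # pragma: no cover - zoom rounding
        raise RuntimeError(f"resample produced {out_img.shape}, "
                           f"expected {(new_d, new_h, new_w)}")
    out_vol = CTVolume(voxels=out_img, spacing=new_spacing, affine=None)

    out_mask = None
    if mask is not None:
        m = (mask.voxels if factors == (1.0, 1.0, 1.0)
             else ndimage.zoom(mask.voxels, factors, order=0, mode="nearest"))
        out_mask = SegmentationMask(voxels=(m > 0).astype(np.uint8),
                                    spacing=new_spacing, affine=None)
    return out_vol, out_mask


def _inplane_transform(arr: np.ndarray, angle_deg: float, scale: float,
                       order: int, cval: float) -> np.ndarray:
    """Rotate about the axial axis and scale in-plane, same output grid."""
    if angle_deg == 0.0 and scale == 1.0:
        return arr
    theta = np.deg2rad(angle_deg)
    c, s = np.cos(theta), np.sin(theta)
    # inverse mapping: output (y, x) -> input; /scale realises magnification
    rot = np.array([[c, -s], [s, c]]) / scale
    mat = np.eye(3)
    mat[1:, 1:] = rot
    center = (np.array(arr.shape) - 1) / 2.0
    offset = center - mat @ center
    return ndimage.affine_transform(arr, mat, offset=offset, order=order,
                                    mode="constant", cval=cval)


def augment(vol: CTVolume, mask: SegmentationMask, spec: AugmentSpec
            ) -> tuple[CTVolume, SegmentationMask]:
    """Apply one random geometric transform jointly to image and mask.

    Deterministic given ``spec.seed``; the mask is re-binarised after the
    nearest-neighbour warp.  Out-of-field voxels are filled with
    ``spec.fill_value`` (the window minimum, i.e. clipped air).
    """
    if not mask.matches_grid(vol):
        raise ValueError("mask grid does not match volume grid")
    shape = vol.shape
    crop = spec.crop_shape or shape
    if any(c > s for c, s in zip(crop, shape)):
        raise ValueError(f"crop shape {crop} exceeds volume shape {shape}")

    rng = np.random.default_rng(spec.seed)
    angle = float(rng.uniform(-spec.rotation_max_deg, spec.rotation_max_deg))
    scale = float(rng.uniform(*spec.scale_range))
    starts = tuple(int(rng.integers(0, s - c + 1)) for c, s in zip(crop, shape))

    img = _inplane_transform(vol.voxels, angle, scale, order=1,
                             cval=spec.fill_value)
    msk = _inplane_transform(mask.voxels.astype(np.float32), angle, scale,
                             order=0, cval=0.0)
    sl = tuple(slice(a, a + c) for a, c in zip(starts, crop))
    out_vol = CTVolume(voxels=img[sl], spacing=vol.spacing, affine=None)
    out_mask = SegmentationMask(voxels=(msk[sl] > 0.5).astype(np.uint8),
                                spacing=vol.spacing, affine=None)
    return out_vol, out_mask


def preprocess_case(vol: CTVolume, mask: SegmentationMask | None,
                    spec: PreprocessSpec
                    ) -> tuple[CTVolume, SegmentationMask | None]:
    """clip -> in-plane resize -> axial respacing, in recipe order."""
    vol = clip_and_normalize(vol, replace(spec, normalize_to_unit=False))
    vol, mask = resample(vol, mask, spec)
    if spec.normalize_to_unit:
        low, high = spec.hu_window
        vol = CTVolume((vol.voxels - low) / (high - low), vol.spacing, vol.affine)
    return vol, mask
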