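"""Synthetic single-organ CT phantoms with ground-truth masks.

Each phantom is a smoothly perturbed ellipsoid ("organ") with liver-like
Hounsfield statistics embedded in a noisier soft-tissue background, wrapped
in an air shell at the volume border, on an anisotropic voxel grid.  The
defaults emulate abdominal CT contrast: foreground ~ N(100, 20) HU versus
background ~ N(-60, 40) HU with 1 mm Gaussian smoothing, which keeps the
organ separable from background by a midpoint intensity threshold (so a
segmentation network can provably learn the task) while leaving realistic
overlap in the intensity histograms.  The air shell guarantees intensities
far outside the [-200, 200] HU liver window, so window clipping is exercised
nontrivially.

Everything is deterministic given the spec seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volume_io import CTVolume, SegmentationMask, write_volume


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity model of one phantom."""

    shape: tuple[int, int, int] = (32, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 0.8, 0.8)
    semi_axes_mm: tuple[float, float, float] = (9.0, 16.0, 14.0)
    center_jitter_mm: float = 2.0
    perturb_amplitude: float = 0.08  # relative radial deformation
    fg_hu: tuple[float, float] = (100.0, 20.0)   # (mean, sd)
    bg_hu: tuple[float, float] = (-60.0, 40.0)
    air_hu: float = -1000.0
    air_border_vox: int = 2
    blur_sigma_mm: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if any(s <= 0 for s in self.shape + self.spacing + self.semi_axes_mm):
            raise ValueError("shape, spacing and semi-axes must be positive")
        if self.fg_hu[1] < 0 or self.bg_hu[1] < 0 or self.blur_sigma_mm < 0:
            raise ValueError("standard deviations and blur sigma must be >= 0")
        if not 0 <= self.perturb_amplitude < 1:
            raise ValueError("perturb_amplitude must be in [0, 1)")
        # organ (with jitter and worst-case outward perturbation) must fit
        # inside the grid with a >= 2-voxel margin
        for ax in range(3):
            extent_mm = (self.shape[ax] - 2 * (2 + self.air_border_vox)) \
                * self.spacing[ax] / 2.0
            reach = (self.semi_axes_mm[ax] * (1 + self.perturb_amplitude)
                     + self.center_jitter_mm)
            if reach > extent_mm:
                raise ValueError(
                    f"organ reach {reach:.1f} mm exceeds grid half-extent "
                    f"{extent_mm:.1f} mm (axis {ax}); enlarge the grid or "
                    f"shrink the organ")


def _smooth_field(shape: tuple[int, int, int],
                  rng: np.random.Generator) -> np.ndarray:
    """Low-frequency random field in [-1, 1] (coarse noise, cubic upsampled)."""
    coarse = rng.normal(size=(4, 4, 4))
    field = ndimage.zoom(coarse, [s / 4 for s in shape], order=3, mode="nearest")
    field = field[: shape[0], : shape[1], : shape[2]]
    m = np.abs(field).max()
    return field / m if m > 0 else field


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, SegmentationMask]:
    """One phantom pair; see module docstring for the generative model."""
    rng = np.random.default_rng(spec.seed)
    shape, spacing = spec.shape, np.asarray(spec.spacing)

    center = (np.asarray(shape) - 1) / 2.0 * spacing
    center += rng.uniform(-spec.center_jitter_mm, spec.center_jitter_mm, size=3)

    grids = np.meshgrid(*[np.arange(s) * sp for s, sp in zip(shape, spacing)],
                        indexing="ij")
    q = np.zeros(shape)
    for g, c, a in zip(grids, center, spec.semi_axes_mm):
        q += ((g - c) / a) ** 2
    q = np.sqrt(q)

    if spec.perturb_amplitude > 0:
        radial_scale = 1.0 + spec.perturb_amplitude * _smooth_field(shape, rng)
    else:
        radial_scale = 1.0
    mask = q <= radial_scale

    labels, ncomp = ndimage.label(mask)
    if ncomp > 1:  # smooth low-amplitude fields keep one component; be safe
        largest = 1 + np.argmax(ndimage.sum_labels(mask, labels,
                                                   range(1, ncomp + 1)))
        mask = labels == largest

    img = rng.normal(spec.bg_hu[0], spec.bg_hu[1], size=shape)
    fg_noise = rng.normal(spec.fg_hu[0], spec.fg_hu[1], size=shape)
    img[mask] = fg_noise[mask]
    if spec.air_border_vox > 0:
        b = spec.air_border_vox
        shell = np.ones(shape, dtype=bool)
        shell[b:-b, b:-b, b:-b] = False
        img[shell] = spec.air_hu
    if spec.blur_sigma_mm > 0:
        img = ndimage.gaussian_filter(img, sigma=spec.blur_sigma_mm / spacing)

    vol = CTVolume(voxels=img.astype(np.float32),
                   spacing=tuple(float(s) for s in spacing))
    gt = SegmentationMask(voxels=mask.astype(np.uint8), spacing=vol.spacing)
    return vol, gt


def analytic_organ_volume_mm3(spec: PhantomSpec) -> float:
    """(4/3)·pi·a·b·c of the unperturbed ellipsoid, in mm^3."""
    a, b, c = spec.semi_axes_mm
    return 4.0 / 3.0 * np.pi * a * b * c


def derive_case_seeds(master_seed: int, n: int) -> list[int]:
    """Independent per-case seeds (< 2^31) from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % (2 ** 31)) for child in ss.spawn(n)]


def generate_dataset(n: int, spec: PhantomSpec, out_dir,
                     master_seed: int | None = None) -> dict:
    """Write ``n`` phantom image/mask NIfTI pairs plus a JSON manifest.

    Per-case seeds are derived from ``master_seed`` (default: ``spec.seed``),
    so re-running with the same master seed reproduces identical files.
    Returns the manifest dict (also written to ``out_dir/manifest.json``).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = spec.seed if master_seed is None else master_seed
    cases = []
    for i, case_seed in enumerate(derive_case_seeds(master, n)):
        case_spec = replace(spec, seed=case_seed)
        vol, mask = generate_phantom(case_spec)
        case_id = f"phantom_{i:03d}"
        img_path = out_dir / f"{case_id}.nii.gz"
        mask_path = out_dir / f"{case_id}_mask.nii.gz"
        write_volume(vol, img_path)
        write_volume(mask, mask_path)
        cases.append({"case_id": case_id,
                      "image": str(img_path),
                      "mask": str(mask_path),
                      "seed": case_seed,
                      "spec": asdict(case_spec)})
    manifest = {"master_seed": master, "n": n, "cases": cases}
    with open(out_dir / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2)
    return manifest
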