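"""Generate a small synthetic CT cohort and inspect it.

Writes three phantom image/mask NIfTI pairs plus a JSON manifest, then
prints the intensity statistics that make the segmentation task well-posed:
organ and background HU distributions overlap but are separable.
"""

import numpy as np

from daunet3d import PhantomSpec, generate_dataset, read_mask, read_volume

manifest = generate_dataset(3, PhantomSpec(seed=0), "scratch/phantoms",
                            master_seed=7)
for case in manifest["cases"]:
    vol = read_volume(case["image"])
    mask = read_mask(case["mask"])
    fg = vol.voxels[mask.voxels == 1]
    bg = vol.voxels[mask.voxels == 0]
    sp = tuple(round(x, 3) for x in vol.spacing)
    print(f"{case['case_id']}: grid {vol.shape} at {sp} mm, "
          f"organ {mask.voxels.sum()} voxels, "
          f"HU fg {fg.mean():.0f}±{fg.std():.0f} vs bg {bg.mean():.0f}±{bg.std():.0f}, "
          f"range [{vol.voxels.min():.0f}, {vol.voxels.max():.0f}]")
print("The organ sits ~160 HU above the soft-tissue background; the air "
      "shell at the border gives values far below the [-200, 200] window.")
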