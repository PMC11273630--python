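"""Probe the attention blocks on a random feature map.

Shows the two facts the architecture relies on: a freshly initialised
dual-attention block is transparent (its learned scale starts at zero), and
its attention maps are probability distributions over source voxels /
channels.  Also applies a CBAM gate and reports its contraction.
"""

import numpy as np

from daunet3d.attention import (CBAM, ChannelAttentionDA, PositionAttention3d)
from daunet3d.nn import Tensor

rng = np.random.default_rng(0)
a = Tensor(rng.standard_normal((4, 2, 3, 3)).astype(np.float32))

pam = PositionAttention3d(4, rng=rng)
cam = ChannelAttentionDA()
print("identity at init (alpha = beta = 0):",
      f"max |PAM(A) - A| = {np.max(np.abs(pam(a).data - a.data)):.2e},",
      f"max |CAM(A) - A| = {np.max(np.abs(cam(a).data - a.data)):.2e}")

s = pam.attention_map(a).data
x = cam.attention_map(a).data
print(f"S is {s.shape[0]}x{s.shape[1]} over voxels, row sums in "
      f"[{s.sum(1).min():.6f}, {s.sum(1).max():.6f}]")
print(f"X is {x.shape[0]}x{x.shape[1]} over channels, row sums in "
      f"[{x.sum(1).min():.6f}, {x.sum(1).max():.6f}]")

gate = CBAM(4, reduction=2, spatial_kernel=3, rng=rng)
out = gate(a).data
print(f"CBAM gating: |output| <= |input| everywhere: "
      f"{bool(np.all(np.abs(out) <= np.abs(a.data) + 1e-7))}; "
      f"mean attenuation {np.mean(np.abs(out) / (np.abs(a.data) + 1e-9)):.2f}")
print("Row-stochastic maps mean each voxel/channel aggregates a convex "
      "combination of all others; the zero scale lets training switch "
      "attention on gradually.")
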