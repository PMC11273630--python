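"""Attention blocks for rank-4 feature maps (C, D, H, W).

Two families are implemented:

* **Dual attention** — a position-attention module (PAM) that softmax-weights
  every voxel by its feature similarity to every other voxel, and a channel
  attention module (CAM) that does the same across channels.  Both add their
  aggregated context back onto the input through a learned scalar scale that
  starts at zero, so a freshly initialised module is an exact identity.  The
  DA-Block runs PAM and CAM in parallel branches at 1/16 channel width and
  fuses them.
* **CBAM** — sequential channel-then-spatial sigmoid gating driven by pooled
  descriptors, applied multiplicatively.

All modules preserve the input shape.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import Tensor
from .nn import autograd as ag


def validate_feature_map(a: Tensor | np.ndarray) -> Tensor:
    """Check a (C, D, H, W) feature map is rank-4 and finite."""
    t = nn.as_tensor(a)
    if t.ndim != 4:
        raise ValueError(f"feature map must be rank-4 (C,D,H,W), got {t.shape}")
    if not np.all(np.isfinite(t.data)):
        raise ValueError("feature map contains non-finite values")
    return t


class PositionAttention3d(nn.Module):
    """Voxel-to-voxel self-attention (DA-PAM).

    Three 1x1x1 convolutions project the input into query/key/value maps
    P, Q, M (each keeping C channels).  The attention matrix
    ``S[j, i] = softmax_i(P'_i . Q'_j)`` holds the influence of voxel i on
    voxel j; the output is ``E_j = alpha * sum_i S[j, i] M'_i + A_j`` with the
    scale ``alpha`` learned from an initial value of 0.
    """

    def __init__(self, channels: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.proj_p = nn.Conv3d(channels, channels, kernel_size=1, rng=rng)
        self.proj_q = nn.Conv3d(channels, channels, kernel_size=1, rng=rng)
        self.proj_m = nn.Conv3d(channels, channels, kernel_size=1, rng=rng)
        self.alpha = nn.Parameter(np.zeros(()))

    def attention_map(self, a: Tensor) -> Tensor:
        """Row-stochastic (N, N) map S; row j weights the sources of voxel j."""
        a = validate_feature_map(a)
        c = a.shape[0]
        n = int(np.prod(a.shape[1:]))
        pf = ag.reshape(self.proj_p(a), (c, n))
        qf = ag.reshape(self.proj_q(a), (c, n))
        logits = ag.matmul(ag.transpose(qf), pf)  # logits[j, i] = Q'_j . P'_i
        return ag.softmax(logits, axis=1)

    def forward(self, a: Tensor) -> Tensor:
        a = validate_feature_map(a)
        c, d, h, w = a.shape
        n = d * h * w
        s = self.attention_map(a)
        mf = ag.reshape(self.proj_m(a), (c, n))
        context = ag.matmul(mf, ag.transpose(s))  # column j = sum_i S[j,i] M'_i
        return self.alpha * ag.reshape(context, (c, d, h, w)) + a


class ChannelAttentionDA(nn.Module):
    """Channel-to-channel self-attention (DA-CAM).

    No learned projections precede the similarity product — the raw input is
    flattened to (C, N) and compared against itself, keeping the original
    channel correlations (and making the block equivariant to channel
    permutations).  ``X[j, i] = softmax_i(A'_i . A'_j)``;
    ``E_j = beta * sum_i X[j, i] A'_i + A_j`` with ``beta`` starting at 0.
    """

    def __init__(self):
        self.beta = nn.Parameter(np.zeros(()))

    def attention_map(self, a: Tensor) -> Tensor:
        """Row-stochastic (C, C) channel-similarity map X."""
        a = validate_feature_map(a)
        c = a.shape[0]
        n = int(np.prod(a.shape[1:]))
        af = ag.reshape(a, (c, n))
        logits = ag.matmul(af, ag.transpose(af))  # symmetric: A'_j . A'_i
        return ag.softmax(logits, axis=1)

    def forward(self, a: Tensor) -> Tensor:
        a = validate_feature_map(a)
        c, d, h, w = a.shape
        x = self.attention_map(a)
        af = ag.reshape(a, (c, d * h * w))
        context = ag.matmul(x, af)  # row j = sum_i X[j,i] A'_i
        return self.beta * ag.reshape(context, (c, d, h, w)) + a


class DABlock(nn.Module):
    """Two-branch dual-attention block.

    Each branch reduces channels to 1/16 of the input width (floored at 1)
    with a 3x3x3 conv block, applies PAM or CAM, convolves again, and the two
    branch outputs are summed and restored to the input width by a 1x1x1
    convolution.  Setting ``bypass_attention`` routes around the PAM/CAM
    cores while keeping every convolution in place (used to verify the
    zero-scale identity of the attention cores).
    """

    def __init__(self, channels: int, reduction: int = 16,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        inner = max(1, channels // reduction)
        self.inner_channels = inner
        self.reduce_pam = nn.ConvNormAct(channels, inner, rng=rng)
        self.reduce_cam = nn.ConvNormAct(channels, inner, rng=rng)
        self.pam = PositionAttention3d(inner, rng=rng)
        self.cam = ChannelAttentionDA()
        self.post_pam = nn.ConvNormAct(inner, inner, rng=rng)
        self.post_cam = nn.ConvNormAct(inner, inner, rng=rng)
        self.restore = nn.Conv3d(inner, channels, kernel_size=1, rng=rng)
        self.bypass_attention = False

    def forward(self, a: Tensor) -> Tensor:
        a = validate_feature_map(a)
        x1 = self.reduce_pam(a)
        x2 = self.reduce_cam(a)
        if not self.bypass_attention:
            x1 = self.pam(x1)
            x2 = self.cam(x2)
        b1 = self.post_pam(x1)
        b2 = self.post_cam(x2)
        return self.restore(b1 + b2)


class CBAMChannelGate(nn.Module):
    """CBAM channel attention: sigmoid of a shared MLP over global max/avg
    pooled channel descriptors, one weight per channel in (0, 1)."""

    def __init__(self, channels: int, reduction: int = 16,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        hidden = max(1, channels // reduction)
        self.w0 = nn.Linear(channels, hidden, bias=False, rng=rng)
        self.w1 = nn.Linear(hidden, channels, bias=False, rng=rng)

    def _mlp(self, desc: Tensor) -> Tensor:
        return self.w1(ag.relu(self.w0(desc)))

    def forward(self, a: Tensor) -> Tensor:
        a = validate_feature_map(a)
        mx = ag.global_maxpool(a)
        av = ag.global_avgpool(a)
        return ag.sigmoid(self._mlp(mx) + self._mlp(av))


class CBAMSpatialGate(nn.Module):
    """CBAM spatial attention: channel-wise max and mean maps stacked and
    convolved (7x7x7 by default) into a single sigmoid weight map."""

    def __init__(self, kernel_size: int = 7,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.conv = nn.Conv3d(2, 1, kernel_size=kernel_size, rng=rng)

    def forward(self, aprime: Tensor) -> Tensor:
        aprime = validate_feature_map(aprime)
        mx = ag.reduce_max(aprime, axis=0, keepdims=True)
        av = ag.reduce_mean(aprime, axis=0, keepdims=True)
        stacked = ag.concat([mx, av], axis=0)
        return ag.sigmoid(self.conv(stacked))


class CBAM(nn.Module):
    """Sequential channel-then-spatial gating: A' = M_c(A) * A, then
    A'' = M_s(A') * A'.  Shape-preserving; with weights in (0,1) every output
    entry is smaller in magnitude than its input."""

    def __init__(self, channels: int, reduction: int = 16,
                 spatial_kernel: int = 7, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.channel_gate = CBAMChannelGate(channels, reduction, rng=rng)
        self.spatial_gate = CBAMSpatialGate(spatial_kernel, rng=rng)

    def forward(self, a: Tensor) -> Tensor:
        a = validate_feature_map(a)
        mc = self.channel_gate(a)
        aprime = ag.reshape(mc, (a.shape[0], 1, 1, 1)) * a
        ms = self.spatial_gate(aprime)
        return ms * aprime
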