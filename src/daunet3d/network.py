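"""Residual 3D U-Net with dual-attention bottleneck and CBAM-gated skips.

The model follows the classic encoder/decoder layout: four residual
downsampling blocks double the channel width and halve every spatial
dimension, a bottleneck of (by default two) DA-Blocks refines the deepest
features, and four residual upsampling blocks restore the input resolution.
Encoder features from the three shallower levels are carried across
concatenating skip connections, optionally gated by a CBAM; a further CBAM
can be applied to the deepest encoder output before the bottleneck.  Every
attention site is an independent config flag so ablation variants (plain
Res-UNet, CBAM-only, DA-only, full model) are all expressible.

Residual blocks implement ``y = F(x) + H(x)`` where F is the resolution
change followed by two conv-norm-ReLU units and H is the same resolution
change followed by an identity (matching widths) or a 1x1x1 convolution.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Literal

import numpy as np

from . import nn
from .attention import CBAM, DABlock
from .nn import Tensor
from .nn import autograd as ag
from .volume_io import CTVolume, SegmentationMask


class ConfigError(ValueError):
    """Inconsistent network configuration."""


class ShapeError(ValueError):
    """Input spatial shape incompatible with the network depth."""


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture description; a checkpoint embeds one so it is self-describing."""

    base_channels: int = 16
    levels: int = 4
    encoder_cbam: bool = False
    skip_cbam: tuple[bool, ...] = (False, False, False)
    bottleneck_da_blocks: int = 2
    out_channels: int = 1
    da_reduction: int = 16
    cbam_reduction: int = 16
    cbam_spatial_kernel: int = 7

    def __post_init__(self):
        if self.levels < 1:
            raise ConfigError("levels must be >= 1")
        if self.base_channels < 1:
            raise ConfigError("base_channels must be >= 1")
        if self.bottleneck_da_blocks < 0:
            raise ConfigError("bottleneck_da_blocks must be >= 0")
        if len(self.skip_cbam) != self.levels - 1:
            raise ConfigError(
                f"skip_cbam needs {self.levels - 1} flags (one per concatenating "
                f"skip), got {len(self.skip_cbam)}")

    @classmethod
    def baseline(cls, **kw) -> "NetworkConfig":
        """Plain 3D Res-UNet: no attention anywhere (ablation baseline)."""
        kw.setdefault("encoder_cbam", False)
        kw.setdefault("bottleneck_da_blocks", 0)
        levels = kw.get("levels", 4)
        kw.setdefault("skip_cbam", (False,) * (levels - 1))
        return cls(**kw)

    @classmethod
    def full_attention(cls, **kw) -> "NetworkConfig":
        """Everything on: encoder CBAM, all skip CBAMs, two DA-Blocks."""
        kw.setdefault("encoder_cbam", True)
        kw.setdefault("bottleneck_da_blocks", 2)
        levels = kw.get("levels", 4)
        kw.setdefault("skip_cbam", (True,) * (levels - 1))
        return cls(**kw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["skip_cbam"] = list(self.skip_cbam)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        d["skip_cbam"] = tuple(d["skip_cbam"])
        return cls(**d)


class ResidualBlock3d(nn.Module):
    """y = F(x) + H(x).

    F: resolution change (2x max-pool on the encoder side, 2x nearest
    upsampling on the decoder side) followed by two conv-norm-ReLU units.
    H: the same resolution change followed by identity when the channel
    widths match, else a 1x1x1 convolution.
    """

    def __init__(self, in_channels: int, out_channels: int,
                 mode: Literal["down", "up"],
                 rng: np.random.Generator | None = None):
        if mode not in ("down", "up"):
            raise ValueError("mode must be 'down' or 'up'")
        rng = rng or np.random.default_rng()
        self.mode = mode
        self.conv1 = nn.ConvNormAct(in_channels, out_channels, rng=rng)
        self.conv2 = nn.ConvNormAct(out_channels, out_channels, rng=rng)
        self.shortcut = (None if in_channels == out_channels
                         else nn.Conv3d(in_channels, out_channels, 1, rng=rng))

    def forward(self, x: Tensor) -> Tensor:
        r = ag.maxpool2(x) if self.mode == "down" else ag.upsample2(x)
        f = self.conv2(self.conv1(r))
        h = r if self.shortcut is None else self.shortcut(r)
        return f + h


class DAResUNet(nn.Module):
    """The assembled segmentation network (see module docstring)."""

    def __init__(self, config: NetworkConfig,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.config = config
        base, levels = config.base_channels, config.levels
        deep = base * 2 ** levels

        self.stem = nn.ConvNormAct(1, base, rng=rng)
        self.encoders = [ResidualBlock3d(base * 2 ** k, base * 2 ** (k + 1),
                                         "down", rng=rng)
                         for k in range(levels)]
        self.encoder_cbam = (CBAM(deep, config.cbam_reduction,
                                  config.cbam_spatial_kernel, rng=rng)
                             if config.encoder_cbam else None)
        self.bottleneck = [DABlock(deep, config.da_reduction, rng=rng)
                           for _ in range(config.bottleneck_da_blocks)]
        self.decoders = [ResidualBlock3d(base * 2 ** (k + 1), base * 2 ** k,
                                         "up", rng=rng)
                         for k in range(levels)]
        self.skip_cbams = [CBAM(base * 2 ** k, config.cbam_reduction,
                                config.cbam_spatial_kernel, rng=rng)
                           if flag else None
                           for k, flag in enumerate(config.skip_cbam)]
        self.fusions = [nn.ConvNormAct(2 * base * 2 ** k, base * 2 ** k, rng=rng)
                        for k in range(levels - 1)]
        self.head = nn.Conv3d(base, config.out_channels, 1, rng=rng)

    # -- helpers ----------------------------------------------------------
    def check_input_shape(self, spatial: tuple[int, int, int]) -> None:
        div = 2 ** self.config.levels
        bad = [s for s in spatial if s % div]
        if bad:
            need = tuple(int(np.ceil(s / div) * div) for s in spatial)
            raise ShapeError(
                f"spatial shape {spatial} not divisible by 2^levels = {div}; "
                f"pad to at least {need}")

    def set_da_bypass(self, bypass: bool) -> None:
        """Route around the PAM/CAM cores of every bottleneck DA-Block."""
        for blk in self.bottleneck:
            blk.bypass_attention = bypass

    def forward(self, x: Tensor | np.ndarray) -> Tensor:
        x = nn.as_tensor(x)
        if x.ndim == 3:
            x = ag.reshape(x, (1,) + x.shape)
        if x.ndim != 4 or x.shape[0] != 1:
            raise ShapeError(f"expected a (1, D, H, W) input, got {x.shape}")
        self.check_input_shape(x.shape[1:])

        t = self.stem(x)
        skips: list[Tensor] = []
        for k, enc in enumerate(self.encoders):
            if k < self.config.levels - 1:
                skips.append(t)  # block input: features at this resolution
            t = enc(t)
        if self.encoder_cbam is not None:
            t = self.encoder_cbam(t)
        for blk in self.bottleneck:
            t = blk(t)
        for k in range(self.config.levels - 1, -1, -1):
            t = self.decoders[k](t)
            if k < self.config.levels - 1:
                s = skips[k]
                if self.skip_cbams[k] is not None:
                    s = self.skip_cbams[k](s)
                t = self.fusions[k](ag.concat([t, s], axis=0))
        return ag.sigmoid(self.head(t))


def build_model(config: NetworkConfig | None = None,
                seed: int | None = None) -> DAResUNet:
    """Construct a seeded, freshly initialised model."""
    return DAResUNet(config or NetworkConfig(),
                     rng=np.random.default_rng(seed))


def predict_mask(model: DAResUNet, vol: CTVolume, threshold: float = 0.5,
                 tile_shape: tuple[int, int, int] | None = None
                 ) -> SegmentationMask:
    """Binarise the model's probability map on (optionally tiled) input.

    Volumes larger than ``tile_shape`` are covered by 50%-overlapping tiles
    whose probabilities are uniformly averaged before thresholding.  A volume
    equal to one tile reproduces untiled inference exactly.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    arr = np.asarray(vol.voxels, dtype=np.float32)
    shape = arr.shape
    tile = tuple(min(t, s) for t, s in zip(tile_shape or shape, shape))
    model.check_input_shape(tile)

    starts = []
    for t, s in zip(tile, shape):
        step = max(1, t // 2)  # 50% overlap
        axis_starts = list(range(0, s - t + 1, step))
        if axis_starts[-1] != s - t:
            axis_starts.append(s - t)
        starts.append(axis_starts)

    prob = np.zeros(shape, dtype=np.float32)
    weight = np.zeros(shape, dtype=np.float32)
    with nn.no_grad():
        for z in starts[0]:
            for y in starts[1]:
                for x in starts[2]:
                    sl = (slice(z, z + tile[0]), slice(y, y + tile[1]),
                          slice(x, x + tile[2]))
                    p = model(arr[sl][None]).data[0]
                    prob[sl] += p
                    weight[sl] += 1.0
    prob /= weight
    return SegmentationMask(voxels=(prob > threshold).astype(np.uint8),
                            spacing=vol.spacing, affine=vol.affine)


def save_checkpoint(model: DAResUNet, path) -> None:
    """Serialise weights with the embedded NetworkConfig (npz + JSON header)."""
    payload = {f"param:{k}": v for k, v in model.state_dict().items()}
    payload["config_json"] = np.array(json.dumps(model.config.to_dict()))
    np.savez(path, **payload)


def load_checkpoint(path) -> DAResUNet:
    with np.load(path, allow_pickle=False) as z:
        config = NetworkConfig.from_dict(json.loads(str(z["config_json"])))
        state = {k[len("param:"):]: z[k] for k in z.files if k.startswith("param:")}
    model = DAResUNet(config, rng=np.random.default_rng(0))
    model.load_state_dict(state)
    return model
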