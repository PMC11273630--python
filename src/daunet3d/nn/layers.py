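"""Layer/module system on top of the autograd engine."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Parameter(Tensor):
    """A trainable tensor; always float32 (the network's working precision)."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)
        # parameters stay trainable even if created under no_grad
        self.requires_grad = True


class Module:
    """Base class; children are discovered through instance attributes."""

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def _children(self) -> Iterator[tuple[str, "Module"]]:
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield prefix + name, val
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for k, p in params.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}: "
                                 f"{p.data.shape} vs {state[k].shape}")
            p.data = np.asarray(state[k], dtype=np.float32).copy()


class Conv3d(Module):
    """Stride-1 'same' 3D convolution for (C, D, H, W) maps, He-initialised."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 bias: bool = True, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        k = kernel_size
        fan_in = in_channels * k ** 3
        std = np.sqrt(2.0 / fan_in)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = k
        self.weight = Parameter(
            rng.normal(0.0, std, size=(out_channels, in_channels, k, k, k)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self._workspace: dict = {}  # im2col scratch reused across calls

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv3d(x, self.weight, self.bias, workspace=self._workspace)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / in_features)
        self.weight = Parameter(rng.normal(0.0, std, size=(out_features, in_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = ag.matmul(self.weight, ag.reshape(x, (x.shape[-1], 1)))
        y = ag.reshape(y, (self.weight.shape[0],))
        if self.bias is not None:
            y = y + self.bias
        return y


class InstanceNorm3d(Module):
    """Per-channel normalisation over the spatial axes with affine gain/bias.

    Chosen over batch statistics because training runs one volume at a time.
    """

    def __init__(self, channels: int, eps: float = 1e-5):
        self.eps = eps
        self.gain = Parameter(np.ones((channels, 1, 1, 1)))
        self.offset = Parameter(np.zeros((channels, 1, 1, 1)))

    def forward(self, x: Tensor) -> Tensor:
        return ag.instance_norm(x, self.gain, self.offset, self.eps)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.relu(x)


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.sigmoid(x)


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.steps = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.steps:
            x = m(x)
        return x


class ConvNormAct(Sequential):
    """Conv -> InstanceNorm -> ReLU, the network's standard unit."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 rng: np.random.Generator | None = None):
        super().__init__(Conv3d(in_channels, out_channels, kernel_size, rng=rng),
                         InstanceNorm3d(out_channels),
                         ReLU())
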