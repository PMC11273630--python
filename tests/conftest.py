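"""Shared fixtures: small deterministic phantoms and tiny network configs."""

from __future__ import annotations

import numpy as np
import pytest

from daunet3d import NetworkConfig, PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """One deterministic phantom pair with the default generator settings."""
    return generate_phantom(PhantomSpec(seed=42))


@pytest.fixture()
def tiny_config():
    """A 2-level, 4-channel model: fast enough for per-test training."""
    return NetworkConfig(base_channels=4, levels=2, encoder_cbam=True,
                         skip_cbam=(True,), bottleneck_da_blocks=1,
                         da_reduction=4, cbam_reduction=4,
                         cbam_spatial_kernel=3)


@pytest.fixture()
def tiny_baseline_config():
    return NetworkConfig.baseline(base_channels=4, levels=2)


def random_mask(rng: np.random.Generator, shape, p=0.3) -> np.ndarray:
    """A random (typically disconnected) binary mask for metric tests."""
    return (rng.random(shape) < p).astype(np.uint8)
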