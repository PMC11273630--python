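"""Model assembly: residual blocks, shape contracts, ablation flags,
attention-at-initialisation identity, tiled inference, checkpoints."""

from __future__ import annotations

import numpy as np
import pytest

from daunet3d.network import (ConfigError, DAResUNet, NetworkConfig,
                              ResidualBlock3d, ShapeError, build_model,
                              load_checkpoint, predict_mask, save_checkpoint)
from daunet3d.nn import Tensor
from daunet3d.volume_io import CTVolume


def test_encoder_block_halves_space_and_doubles_channels():
    rng = np.random.default_rng(0)
    blk = ResidualBlock3d(16, 32, "down", rng=rng)
    out = blk(Tensor(rng.standard_normal((16, 32, 64, 64)).astype(np.float32)))
    assert out.shape == (32, 16, 32, 32)

    up = ResidualBlock3d(32, 16, "up", rng=rng)
    assert up(Tensor(np.zeros((32, 4, 4, 4), np.float32))).shape == (16, 8, 8, 8)


def test_residual_block_zero_main_path_reduces_to_shortcut():
    """With F's weights zeroed and matching widths (H = identity), the block
    is exactly the resolution change of its input."""
    rng = np.random.default_rng(1)
    blk = ResidualBlock3d(8, 8, "down", rng=rng)
    for conv in (blk.conv1, blk.conv2):
        conv.steps[0].weight.data[:] = 0.0
        conv.steps[1].offset.data[:] = 0.0
    assert blk.shortcut is None
    x = rng.standard_normal((8, 4, 4, 4)).astype(np.float32)
    from daunet3d.nn import autograd as ag
    np.testing.assert_allclose(blk(Tensor(x)).data,
                               ag.maxpool2(Tensor(x)).data, atol=1e-7)


def test_residual_block_odd_dimension_rejected():
    blk = ResidualBlock3d(4, 8, "down", rng=np.random.default_rng(2))
    with pytest.raises(ValueError, match="even"):
        blk(Tensor(np.zeros((4, 3, 4, 4), np.float32)))


def test_gradient_flows_through_both_residual_paths():
    """d(sum y)/dx equals the sum of the two path-wise derivatives."""
    rng = np.random.default_rng(3)
    blk = ResidualBlock3d(2, 4, "down", rng=rng)
    x = Tensor(rng.standard_normal((2, 4, 4, 4)).astype(np.float32),
               requires_grad=True)
    y = blk(x)
    y.sum().backward()
    analytic = x.grad.copy()

    eps = 1e-2
    for _ in range(4):
        idx = tuple(rng.integers(0, s) for s in x.shape)
        orig = float(x.data[idx])
        x.data[idx] = orig + eps
        fp = float(blk(Tensor(x.data)).data.sum())
        x.data[idx] = orig - eps
        fm = float(blk(Tensor(x.data)).data.sum())
        x.data[idx] = orig
        assert analytic[idx] == pytest.approx((fp - fm) / (2 * eps),
                                              rel=5e-2, abs=1e-2)


def test_config_validation_and_ablation_reachability():
    with pytest.raises(ConfigError, match="skip_cbam"):
        NetworkConfig(levels=4, skip_cbam=(True,))
    with pytest.raises(ConfigError):
        NetworkConfig(levels=0, skip_cbam=())

    # every attention-placement row is a distinct constructible config:
    # baseline, encoder-CBAM only, each single skip, all skips, everything
    rows = [NetworkConfig.baseline(),
            NetworkConfig(encoder_cbam=True, bottleneck_da_blocks=0),
            *[NetworkConfig(bottleneck_da_blocks=0,
                            skip_cbam=tuple(i == k for i in range(3)))
              for k in range(3)],
            NetworkConfig(bottleneck_da_blocks=0, skip_cbam=(True,) * 3),
            NetworkConfig(encoder_cbam=True, bottleneck_da_blocks=0,
                          skip_cbam=(True,) * 3),
            NetworkConfig(bottleneck_da_blocks=2),  # DA-only row
            NetworkConfig.full_attention()]
    assert len({repr(c) for c in rows}) == len(rows)


def test_parameter_count_strictly_increases_with_each_attention_site(
        tiny_baseline_config):
    base = build_model(tiny_baseline_config, seed=0).num_parameters()
    enc = build_model(NetworkConfig.baseline(base_channels=4, levels=2,
                                             encoder_cbam=True),
                      seed=0).num_parameters()
    skip = build_model(NetworkConfig.baseline(base_channels=4, levels=2,
                                              skip_cbam=(True,)),
                       seed=0).num_parameters()
    da = build_model(NetworkConfig.baseline(base_channels=4, levels=2,
                                            bottleneck_da_blocks=1),
                     seed=0).num_parameters()
    assert enc > base and skip > base and da > base
    assert build_model(NetworkConfig(base_channels=4, levels=2,
                                     encoder_cbam=True, skip_cbam=(True,),
                                     bottleneck_da_blocks=1),
                       seed=0).num_parameters() > max(enc, skip, da)


def test_baseline_config_has_no_attention_modules(tiny_baseline_config):
    model = build_model(tiny_baseline_config, seed=0)
    assert model.encoder_cbam is None
    assert model.bottleneck == []
    assert all(c is None for c in model.skip_cbams)


def test_forward_shape_contract_and_probability_range(tiny_config):
    model = build_model(tiny_config, seed=0)
    for shape in ((4, 8, 8), (8, 8, 12), (4, 16, 8)):
        out = model(np.random.default_rng(0).random((1, *shape),
                                                    dtype=np.float32))
        assert out.shape == (1, *shape)
        assert np.all((out.data > 0) & (out.data < 1))


def test_forward_rejects_indivisible_shapes_with_padding_hint(tiny_config):
    model = build_model(tiny_config, seed=0)
    with pytest.raises(ShapeError, match="pad to at least"):
        model(np.zeros((1, 5, 8, 8), np.float32))


def test_forward_is_deterministic(tiny_config):
    model = build_model(tiny_config, seed=0)
    x = np.random.default_rng(1).random((1, 4, 8, 8), dtype=np.float32)
    np.testing.assert_array_equal(model(x).data, model(x).data)


def test_da_attention_at_initialisation_is_transparent(tiny_config):
    """With the attention scales at their zero initialisation, routing
    around the PAM/CAM cores does not change the network output."""
    model = build_model(tiny_config, seed=3)
    x = np.random.default_rng(2).random((1, 4, 8, 8), dtype=np.float32)
    with_attention = model(x).data
    model.set_da_bypass(True)
    without = model(x).data
    np.testing.assert_allclose(with_attention, without, atol=1e-5)


def test_seeded_build_is_reproducible(tiny_config):
    m1 = build_model(tiny_config, seed=11)
    m2 = build_model(tiny_config, seed=11)
    for (k1, p1), (k2, p2) in zip(m1.named_parameters(), m2.named_parameters()):
        assert k1 == k2
        np.testing.assert_array_equal(p1.data, p2.data)


class _ConstantModel:
    """Stub emitting a constant probability; exercises thresholding only."""

    def __init__(self, value, levels=1):
        self.value = value
        self.config = NetworkConfig(base_channels=1, levels=levels,
                                    skip_cbam=(False,) * (levels - 1),
                                    bottleneck_da_blocks=0)

    def check_input_shape(self, spatial):
        DAResUNet.check_input_shape(self, spatial)

    def __call__(self, x):
        return Tensor(np.full_like(np.asarray(x), self.value))


def test_predict_mask_thresholding():
    vol = CTVolume(np.zeros((4, 8, 8)), spacing=(1, 1, 1))
    high = predict_mask(_ConstantModel(0.9), vol, threshold=0.5)
    assert np.all(high.voxels == 1)
    low = predict_mask(_ConstantModel(0.1), vol, threshold=0.5)
    assert np.all(low.voxels == 0)
    with pytest.raises(ValueError, match="threshold"):
        predict_mask(_ConstantModel(0.5), vol, threshold=1.5)


def test_tiled_inference_single_tile_matches_untiled(tiny_config):
    model = build_model(tiny_config, seed=5)
    arr = np.random.default_rng(3).random((4, 8, 8), dtype=np.float32)
    vol = CTVolume(arr, spacing=(1, 1, 1))
    untiled = predict_mask(model, vol, tile_shape=None)
    tiled = predict_mask(model, vol, tile_shape=(4, 8, 8))
    np.testing.assert_array_equal(untiled.voxels, tiled.voxels)


def test_tiled_inference_covers_larger_volume(tiny_config):
    model = build_model(tiny_config, seed=6)
    arr = np.random.default_rng(4).random((8, 16, 16), dtype=np.float32)
    vol = CTVolume(arr, spacing=(1, 1, 1))
    mask = predict_mask(model, vol, tile_shape=(4, 8, 8))
    assert mask.shape == (8, 16, 16)
    assert set(np.unique(mask.voxels)) <= {0, 1}


def test_checkpoint_round_trip_preserves_predictions(tmp_path, tiny_config):
    model = build_model(tiny_config, seed=7)
    x = np.random.default_rng(5).random((1, 4, 8, 8), dtype=np.float32)
    before = model(x).data
    save_checkpoint(model, tmp_path / "ckpt.npz")
    restored = load_checkpoint(tmp_path / "ckpt.npz")
    assert restored.config == tiny_config
    np.testing.assert_allclose(restored(x).data, before, atol=1e-7)


def test_fresh_model_finite_outputs_and_gradients(tiny_config):
    from daunet3d.losses import tversky_loss
    model = build_model(tiny_config, seed=8)
    rng = np.random.default_rng(6)
    x = rng.random((1, 4, 8, 8), dtype=np.float32)
    gt = (rng.random((1, 4, 8, 8)) < 0.5).astype(np.float32)
    out = model(x)
    assert np.all(np.isfinite(out.data))
    loss = tversky_loss(out, gt)
    model.zero_grad()
    loss.backward()
    grads = [p.grad for p in model.parameters()]
    assert all(g is not None and np.all(np.isfinite(g)) for g in grads)
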