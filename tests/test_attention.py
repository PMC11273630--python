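"""Attention blocks versus explicit-loop reference computations.

Every attention operation is checked against a brute-force oracle that
evaluates its defining formula with plain Python loops over all voxel /
channel pairs — the oracle shares no code with the vectorised
implementation under test.
"""

from __future__ import annotations

import numpy as np
import pytest

from daunet3d.attention import (CBAM, CBAMChannelGate, CBAMSpatialGate,
                                ChannelAttentionDA, DABlock,
                                PositionAttention3d)
from daunet3d.nn import Tensor

N_TRIALS = 100


def rand_map(rng, c, d, h, w):
    return rng.standard_normal((c, d, h, w)).astype(np.float32)


def small_shapes(rng, n):
    for _ in range(n):
        yield (int(rng.integers(1, 5)), int(rng.integers(1, 4)),
               int(rng.integers(1, 4)), int(rng.integers(1, 4)))


# -- brute-force oracles ---------------------------------------------------

def oracle_pam(a, wp, bp, wq, bq, wm, bm, alpha):
    """Voxel-pair position attention by explicit loops."""
    c = a.shape[0]
    n = a[0].size
    af = a.reshape(c, n).astype(np.float64)
    proj = {}
    for name, (wmat, bvec) in {"p": (wp, bp), "q": (wq, bq),
                               "m": (wm, bm)}.items():
        out = np.zeros((c, n))
        for ci in range(c):
            for v in range(n):
                out[ci, v] = sum(wmat[ci, cj] * af[cj, v] for cj in range(c)) \
                    + bvec[ci]
        proj[name] = out
    p, q, m = proj["p"], proj["q"], proj["m"]
    s = np.zeros((n, n))
    for j in range(n):
        logits = [np.exp(np.dot(p[:, i], q[:, j])) for i in range(n)]
        total = sum(logits)
        for i in range(n):
            s[j, i] = logits[i] / total
    e = np.zeros((c, n))
    for j in range(n):
        ctx = sum(s[j, i] * m[:, i] for i in range(n))
        e[:, j] = alpha * ctx + af[:, j]
    return e.reshape(a.shape), s


def oracle_cam(a, beta):
    """Channel-pair attention by explicit loops."""
    c = a.shape[0]
    n = a[0].size
    af = a.reshape(c, n).astype(np.float64)
    x = np.zeros((c, c))
    for j in range(c):
        logits = [np.exp(np.dot(af[i], af[j])) for i in range(c)]
        total = sum(logits)
        for i in range(c):
            x[j, i] = logits[i] / total
    e = np.zeros((c, n))
    for j in range(c):
        e[j] = beta * sum(x[j, i] * af[i] for i in range(c)) + af[j]
    return e.reshape(a.shape), x


def oracle_cbam_channel(a, w0, w1):
    """Sigmoid of the shared MLP over max/avg pooled descriptors."""
    c = a.shape[0]
    mx = np.array([a[ci].max() for ci in range(c)], dtype=np.float64)
    av = np.array([a[ci].mean() for ci in range(c)], dtype=np.float64)

    def mlp(desc):
        hidden = np.maximum(w0.astype(np.float64) @ desc, 0.0)
        return w1.astype(np.float64) @ hidden

    return 1.0 / (1.0 + np.exp(-(mlp(mx) + mlp(av))))


def oracle_cbam_spatial(a, kernel, bias):
    """Channel-pooled maps stacked, convolved (zero padded), sigmoided."""
    _, d, h, w = a.shape
    stacked = np.stack([a.max(axis=0), a.mean(axis=0)]).astype(np.float64)
    k = kernel.shape[-1]
    p = k // 2
    out = np.zeros((d, h, w))
    for z in range(d):
        for y in range(h):
            for x in range(w):
                acc = bias
                for ci in range(2):
                    for dz in range(k):
                        for dy in range(k):
                            for dx in range(k):
                                zz, yy, xx = z + dz - p, y + dy - p, x + dx - p
                                if 0 <= zz < d and 0 <= yy < h and 0 <= xx < w:
                                    acc += kernel[0, ci, dz, dy, dx] \
                                        * stacked[ci, zz, yy, xx]
                out[z, y, x] = 1.0 / (1.0 + np.exp(-acc))
    return out[None]


# -- DA-PAM ----------------------------------------------------------------

def test_position_attention_matches_loop_oracle():
    rng = np.random.default_rng(1)
    for c, d, h, w in small_shapes(rng, N_TRIALS):
        pam = PositionAttention3d(c, rng=rng)
        pam.alpha.data = np.asarray(rng.normal(), dtype=np.float32)
        a = rand_map(rng, c, d, h, w)
        got = pam(Tensor(a)).data
        want, s_ref = oracle_pam(
            a,
            pam.proj_p.weight.data[:, :, 0, 0, 0], pam.proj_p.bias.data,
            pam.proj_q.weight.data[:, :, 0, 0, 0], pam.proj_q.bias.data,
            pam.proj_m.weight.data[:, :, 0, 0, 0], pam.proj_m.bias.data,
            float(pam.alpha.data))
        np.testing.assert_allclose(got, want, atol=1e-4, rtol=1e-4)
        np.testing.assert_allclose(pam.attention_map(Tensor(a)).data, s_ref,
                                   atol=1e-5)


def test_position_attention_zero_scale_is_exact_identity():
    rng = np.random.default_rng(2)
    pam = PositionAttention3d(3, rng=rng)  # alpha starts at 0
    a = rand_map(rng, 3, 2, 3, 2)
    assert np.array_equal(pam(Tensor(a)).data, a)


def test_position_attention_single_voxel_softmax_degenerates():
    rng = np.random.default_rng(3)
    pam = PositionAttention3d(2, rng=rng)
    pam.alpha.data = np.asarray(0.5, dtype=np.float32)
    a = rand_map(rng, 2, 1, 1, 1)
    s = pam.attention_map(Tensor(a)).data
    np.testing.assert_allclose(s, [[1.0]], atol=1e-7)
    mprime = pam.proj_m(Tensor(a)).data
    np.testing.assert_allclose(pam(Tensor(a)).data, 0.5 * mprime + a,
                               atol=1e-6)


# -- DA-CAM ----------------------------------------------------------------

def test_channel_attention_matches_loop_oracle():
    rng = np.random.default_rng(4)
    for c, d, h, w in small_shapes(rng, N_TRIALS):
        cam = ChannelAttentionDA()
        cam.beta.data = np.asarray(rng.normal(), dtype=np.float32)
        a = rand_map(rng, c, d, h, w)
        want, x_ref = oracle_cam(a, float(cam.beta.data))
        np.testing.assert_allclose(cam(Tensor(a)).data, want,
                                   atol=1e-4, rtol=1e-4)
        np.testing.assert_allclose(cam.attention_map(Tensor(a)).data, x_ref,
                                   atol=1e-5)


def test_channel_attention_zero_scale_and_single_channel():
    rng = np.random.default_rng(5)
    cam = ChannelAttentionDA()
    a = rand_map(rng, 3, 2, 2, 2)
    assert np.array_equal(cam(Tensor(a)).data, a)  # beta = 0

    cam.beta.data = np.asarray(0.7, dtype=np.float32)
    single = rand_map(rng, 1, 2, 2, 2)
    np.testing.assert_allclose(cam.attention_map(Tensor(single)).data, [[1.0]])
    np.testing.assert_allclose(cam(Tensor(single)).data, 1.7 * single,
                               rtol=1e-6)


def test_channel_attention_is_channel_permutation_equivariant():
    rng = np.random.default_rng(6)
    cam = ChannelAttentionDA()
    cam.beta.data = np.asarray(0.9, dtype=np.float32)
    a = rand_map(rng, 4, 2, 3, 2)
    perm = rng.permutation(4)
    out_perm = cam(Tensor(a[perm])).data
    np.testing.assert_allclose(out_perm, cam(Tensor(a)).data[perm], atol=1e-5)


def test_attention_maps_are_row_stochastic():
    rng = np.random.default_rng(7)
    for c, d, h, w in small_shapes(rng, N_TRIALS):
        a = rand_map(rng, c, d, h, w)
        s = PositionAttention3d(c, rng=rng).attention_map(Tensor(a)).data
        x = ChannelAttentionDA().attention_map(Tensor(a)).data
        for m in (s, x):
            assert np.all(m >= 0)
            np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-5)


# -- DA-Block --------------------------------------------------------------

def test_da_block_reduces_channels_sixteen_fold_and_preserves_shape():
    rng = np.random.default_rng(8)
    blk = DABlock(32, rng=rng)
    assert blk.inner_channels == 2  # 32 / 16
    a = rand_map(rng, 32, 4, 4, 4)
    assert blk(Tensor(a)).data.shape == a.shape
    assert DABlock(8, rng=rng).inner_channels == 1  # floored at 1


def test_da_block_matches_stepwise_reference():
    """Block output equals the hand-chained sub-operations with the same
    weights, with the PAM/CAM cores replaced by their loop oracles."""
    rng = np.random.default_rng(9)
    blk = DABlock(32, rng=rng)
    blk.pam.alpha.data = np.asarray(0.3, dtype=np.float32)
    blk.cam.beta.data = np.asarray(-0.4, dtype=np.float32)
    a = rand_map(rng, 32, 4, 4, 4)

    x1 = blk.reduce_pam(Tensor(a)).data
    pam_out, _ = oracle_pam(
        x1,
        blk.pam.proj_p.weight.data[:, :, 0, 0, 0], blk.pam.proj_p.bias.data,
        blk.pam.proj_q.weight.data[:, :, 0, 0, 0], blk.pam.proj_q.bias.data,
        blk.pam.proj_m.weight.data[:, :, 0, 0, 0], blk.pam.proj_m.bias.data,
        0.3)
    x2 = blk.reduce_cam(Tensor(a)).data
    cam_out, _ = oracle_cam(x2, -0.4)
    b1 = blk.post_pam(Tensor(pam_out.astype(np.float32))).data
    b2 = blk.post_cam(Tensor(cam_out.astype(np.float32))).data
    want = blk.restore(Tensor(b1 + b2)).data
    np.testing.assert_allclose(blk(Tensor(a)).data, want, atol=1e-5)


def test_da_block_bypass_equals_zero_scale_attention():
    rng = np.random.default_rng(10)
    blk = DABlock(16, rng=rng)  # alpha = beta = 0 at init
    a = rand_map(rng, 16, 2, 4, 4)
    full = blk(Tensor(a)).data
    blk.bypass_attention = True
    np.testing.assert_allclose(blk(Tensor(a)).data, full, atol=1e-6)


# -- CBAM ------------------------------------------------------------------

def test_cbam_channel_matches_arithmetic_oracle():
    rng = np.random.default_rng(11)
    for _ in range(N_TRIALS):
        c = int(rng.integers(1, 5))
        gate = CBAMChannelGate(c, reduction=2, rng=rng)
        a = rand_map(rng, c, 2, 2, 2)
        want = oracle_cbam_channel(a, gate.w0.weight.data, gate.w1.weight.data)
        np.testing.assert_allclose(gate(Tensor(a)).data, want, atol=1e-6)


def test_cbam_channel_degenerate_cases():
    rng = np.random.default_rng(12)
    gate = CBAMChannelGate(4, reduction=2, rng=rng)
    a = rand_map(rng, 4, 2, 2, 2)

    gate.w0.weight.data = np.zeros_like(gate.w0.weight.data)
    gate.w1.weight.data = np.zeros_like(gate.w1.weight.data)
    np.testing.assert_allclose(gate(Tensor(a)).data, 0.5)  # sigmoid(0)

    gate2 = CBAMChannelGate(4, reduction=2, rng=rng)
    const = np.tile(rng.standard_normal((4, 1, 1, 1)).astype(np.float32),
                    (1, 2, 2, 2))  # spatially constant: max pool == avg pool
    desc = const[:, 0, 0, 0]
    hidden = np.maximum(gate2.w0.weight.data @ desc, 0)
    want = 1 / (1 + np.exp(-2 * (gate2.w1.weight.data @ hidden)))
    np.testing.assert_allclose(gate2(Tensor(const)).data, want, atol=1e-6)


def test_cbam_spatial_matches_arithmetic_oracle():
    rng = np.random.default_rng(13)
    for _ in range(20):  # the 7-loop oracle is slow; 20 trials suffice
        c = int(rng.integers(1, 5))
        gate = CBAMSpatialGate(kernel_size=3, rng=rng)
        a = rand_map(rng, c, 3, 3, 3)
        want = oracle_cbam_spatial(a, gate.conv.weight.data,
                                   float(gate.conv.bias.data[0]))
        np.testing.assert_allclose(gate(Tensor(a)).data, want, atol=1e-6)


def test_cbam_spatial_degenerate_cases():
    rng = np.random.default_rng(14)
    gate = CBAMSpatialGate(kernel_size=3, rng=rng)
    gate.conv.weight.data = np.zeros_like(gate.conv.weight.data)
    a = rand_map(rng, 3, 2, 3, 2)
    np.testing.assert_allclose(gate(Tensor(a)).data, 0.5)  # zero kernel

    single = rand_map(rng, 1, 2, 2, 2)  # C=1: max map == avg map == input
    from daunet3d.nn import autograd as ag
    mx = ag.reduce_max(Tensor(single), axis=0, keepdims=True).data
    av = ag.reduce_mean(Tensor(single), axis=0, keepdims=True).data
    np.testing.assert_allclose(mx, single)
    np.testing.assert_allclose(av, single)


def test_cbam_composition_and_contraction():
    rng = np.random.default_rng(15)
    cbam = CBAM(4, reduction=2, spatial_kernel=3, rng=rng)
    a = rand_map(rng, 4, 3, 3, 3)
    out = cbam(Tensor(a)).data

    mc = cbam.channel_gate(Tensor(a)).data
    aprime = mc[:, None, None, None] * a
    ms = cbam.spatial_gate(Tensor(aprime)).data
    np.testing.assert_allclose(out, ms * aprime, atol=1e-6)

    assert np.all(np.abs(out) <= np.abs(a) + 1e-7)  # weights in (0,1)
    assert np.all((mc > 0) & (mc < 1)) and np.all((ms > 0) & (ms < 1))


def test_attention_rejects_non_finite_input():
    bad = np.ones((2, 2, 2, 2), dtype=np.float32)
    bad[0, 0, 0, 0] = np.nan
    with pytest.raises(ValueError, match="finite"):
        ChannelAttentionDA()(Tensor(bad))
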