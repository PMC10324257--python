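"""Channel/spatial attention vs independent brute-force pooled oracles."""

from __future__ import annotations

import numpy as np
import pytest
from PIL import Image

from ocusiam.attention import (
    AttentionConfig,
    CBAM,
    ChannelAttention,
    SpatialAttention,
    export_attention_overlay,
)
from ocusiam.nn import Tensor


def channel_attention_oracle(f: np.ndarray, ca: ChannelAttention) -> np.ndarray:
    """Straight-line recomputation: pools, shared MLP, add, sigmoid."""
    n, c, h, w = f.shape
    w1, b1 = ca.fc1.weight.data, ca.fc1.bias.data
    w2, b2 = ca.fc2.weight.data, ca.fc2.bias.data

    def mlp(v):
        return np.maximum(v @ w1.T + b1, 0.0) @ w2.T + b2

    avg = f.reshape(n, c, -1).mean(axis=2)
    mx = f.reshape(n, c, -1).max(axis=2)
    return 1.0 / (1.0 + np.exp(-(mlp(avg) + mlp(mx))))


def spatial_attention_oracle(f: np.ndarray, sa: SpatialAttention) -> np.ndarray:
    """Per-pixel channel pools + direct convolution loop."""
    n, c, h, w = f.shape
    k = sa.conv.kernel_size
    pad = (k - 1) // 2
    desc = np.stack([f.mean(axis=1), f.max(axis=1)], axis=1)  # (n,2,h,w)
    padded = np.pad(desc, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    wgt = sa.conv.weight.data.reshape(1, 2, k, k)
    out = np.zeros((n, 1, h, w))
    for b in range(n):
        for i in range(h):
            for j in range(w):
                out[b, 0, i, j] = (
                    padded[b, :, i : i + k, j : j + k] * wgt[0]
                ).sum() + sa.conv.bias.data[0]
    return 1.0 / (1.0 + np.exp(-out))


@pytest.mark.parametrize("shape", [(1, 3, 4, 5), (2, 6, 3, 3), (1, 1, 5, 4)])
def test_channel_attention_matches_bruteforce_oracle(shape, rng):
    ca = ChannelAttention(shape[1], reduction=2, rng=rng)
    for _ in range(20):
        f = rng.normal(size=shape)
        got = ca(Tensor(f)).data[:, :, 0, 0]
        assert np.allclose(got, channel_attention_oracle(f, ca), atol=1e-6)


@pytest.mark.parametrize("kernel", [3, 7])
def test_spatial_attention_matches_bruteforce_oracle(kernel, rng):
    sa = SpatialAttention(kernel, rng)
    for _ in range(10):
        f = rng.normal(size=(2, 4, 5, 6))
        got = sa(Tensor(f)).data
        assert np.allclose(got, spatial_attention_oracle(f, sa), atol=1e-6)


def test_constant_feature_doubles_the_shared_mlp_output(rng):
    """Spatially constant F: avg and max pools agree, so the logit is 2*MLP(c)."""
    c = 4
    ca = ChannelAttention(c, reduction=2, rng=rng)
    vec = rng.normal(size=c)
    f = np.broadcast_to(vec[None, :, None, None], (1, c, 3, 5)).copy()
    got = ca(Tensor(f)).data[0, :, 0, 0]
    w1, b1 = ca.fc1.weight.data, ca.fc1.bias.data
    w2, b2 = ca.fc2.weight.data, ca.fc2.bias.data
    logit = 2 * (np.maximum(vec @ w1.T + b1, 0.0) @ w2.T + b2)
    assert np.allclose(got, 1 / (1 + np.exp(-logit)), atol=1e-10)


def test_zero_parameters_give_half_maps(rng):
    ca = ChannelAttention(5, reduction=2, rng=rng)
    sa = SpatialAttention(7, rng)
    for p in [*ca.parameters(), *sa.parameters()]:
        p.data[:] = 0.0
    f = rng.normal(size=(2, 5, 6, 6))
    assert np.allclose(ca(Tensor(f)).data, 0.5)
    assert np.allclose(sa(Tensor(f)).data, 0.5)


def test_attention_map_shapes_and_open_interval(rng):
    f = rng.normal(size=(3, 8, 5, 7)) * 10
    ca = ChannelAttention(8, 16, rng)
    sa = SpatialAttention(7, rng)
    mc = ca(Tensor(f)).data
    ms = sa(Tensor(f)).data
    assert mc.shape == (3, 8, 1, 1) and ms.shape == (3, 1, 5, 7)
    for m in (mc, ms):
        assert (m > 0).all() and (m < 1).all()


def test_channel_attention_invariant_to_spatial_permutation(rng):
    ca = ChannelAttention(4, 2, rng)
    f = rng.normal(size=(1, 4, 3, 5))
    perm = rng.permutation(15)
    shuffled = f.reshape(1, 4, 15)[:, :, perm].reshape(1, 4, 3, 5)
    assert np.allclose(ca(Tensor(f)).data, ca(Tensor(shuffled)).data, atol=1e-12)


def test_spatial_attention_invariant_to_channel_permutation(rng):
    sa = SpatialAttention(3, rng)
    f = rng.normal(size=(1, 6, 4, 4))
    perm = rng.permutation(6)
    assert np.allclose(sa(Tensor(f)).data, sa(Tensor(f[:, perm])).data, atol=1e-12)


class TestCBAM:
    def test_disabled_block_is_identity(self, rng):
        block = CBAM(4, AttentionConfig(channel=False, spatial=False), rng)
        f = rng.normal(size=(2, 4, 5, 5))
        assert np.array_equal(block(Tensor(f)).data, f)

    def test_zero_parameters_quarter_the_input(self, rng):
        block = CBAM(4, AttentionConfig(reduction=2), rng)
        for p in block.parameters():
            p.data[:] = 0.0
        f = rng.normal(size=(1, 4, 6, 6))
        assert np.allclose(block(Tensor(f)).data, 0.25 * f, atol=1e-12)

    def test_zero_input_is_annihilated(self, rng):
        block = CBAM(3, AttentionConfig(reduction=1), rng)
        out = block(Tensor(np.zeros((1, 3, 4, 4)))).data
        assert np.array_equal(out, np.zeros((1, 3, 4, 4)))

    def test_refinement_never_grows_magnitude_or_changes_shape(self, rng):
        block = CBAM(5, AttentionConfig(reduction=2), rng)
        f = rng.normal(size=(2, 5, 4, 6))
        out = block(Tensor(f)).data
        assert out.shape == f.shape
        assert (np.abs(out) <= np.abs(f) + 1e-12).all()

    def test_even_spatial_kernel_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            AttentionConfig(spatial_kernel=4)


class TestOverlay:
    def test_overlay_roundtrip_matches_image_dimensions(self, tmp_path, rng):
        img = rng.normal(size=(3, 16, 16))
        m = rng.random((1, 4, 4))
        p = tmp_path / "overlay.png"
        export_attention_overlay(img, m, p)
        with Image.open(p) as im:
            assert im.size == (16, 16)

    def test_uniform_map_gives_spatially_constant_tint(self, tmp_path):
        img = np.zeros((3, 8, 8))
        p = tmp_path / "uniform.png"
        export_attention_overlay(img, np.full((1, 2, 2), 0.5), p)
        arr = np.asarray(Image.open(p))
        assert (arr == arr[0, 0]).all()

    def test_single_peak_survives_upsampling(self, tmp_path, rng):
        img = np.zeros((1, 32, 32))
        m = np.zeros((1, 8, 8))
        m[0, 2, 5] = 1.0
        p = tmp_path / "peak.png"
        export_attention_overlay(img, m, p, alpha=1.0)
        arr = np.asarray(Image.open(p)).astype(float)
        # red channel of the jet colormap peaks where the map peaks
        intensity = arr[..., 0]
        peak = np.unravel_index(intensity.argmax(), intensity.shape)
        assert abs(peak[0] - 2 * 4) <= 4 and abs(peak[1] - 5 * 4) <= 4
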