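"""Building-block tests: stem, ConvNeXt/GRN, windows, attention, resampling.

The attention, GRN and depthwise-convolution paths are checked against
independent brute-force oracles written as plain loops over indices.
"""

import numpy as np
import pytest

from octfluidseg import autodiff as ad
from octfluidseg.autodiff import Tensor
from octfluidseg.core_blocks import (GRN, ConvNeXtBlock, Downsample, Stem,
                                     TransformerBlock, Upsample, WindowMSA,
                                     grn, window_merge, window_partition)


# ---------------------------------------------------------------------------
# oracles (independent loop implementations)
# ---------------------------------------------------------------------------

def loop_conv2d(x, w, b=None, stride=1, padding=1, groups=1):
    """Naive nested-loop cross-correlation, NCHW / OIHW."""
    B, Cin, H, W = x.shape
    Cout, Cin_g, kh, kw = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    Ho = (H + 2 * padding - kh) // stride + 1
    Wo = (W + 2 * padding - kw) // stride + 1
    out = np.zeros((B, Cout, Ho, Wo))
    per_group = Cout // groups
    for bi in range(B):
        for o in range(Cout):
            g = o // per_group
            for i in range(Cin_g):
                ci = g * Cin_g + i
                for y in range(Ho):
                    for xo in range(Wo):
                        patch = xp[bi, ci, y * stride:y * stride + kh,
                                   xo * stride:xo * stride + kw]
                        out[bi, o, y, xo] += float((patch * w[o, i]).sum())
            if b is not None:
                out[bi, o] += b[o]
    return out


def loop_attention(tokens, wq, wk, wv, wo, bq, bk, bv, bo, pos, heads):
    """Brute-force windowed self-attention for one window of tokens (T, C)."""
    T, C = tokens.shape
    dk = C // heads
    Q, K, V = tokens @ wq + bq, tokens @ wk + bk, tokens @ wv + bv
    out = np.zeros((T, C))
    for h in range(heads):
        sl = slice(h * dk, (h + 1) * dk)
        Qh, Kh, Vh = Q[:, sl], K[:, sl], V[:, sl]
        for t in range(T):
            logits = np.array([Qh[t] @ Kh[u] / np.sqrt(dk) for u in range(T)])
            e = np.exp(logits - logits.max())
            a = e / e.sum()
            out[t, sl] = sum(a[u] * Vh[u] for u in range(T))
    return out @ wo + bo + pos


def loop_grn(x, gain, bias, eps=1e-6):
    """Two-pass evaluation of global response normalization, (B, H, W, C)."""
    B, H, W, C = x.shape
    out = np.empty_like(x)
    for b in range(B):
        G = np.array([np.sqrt((x[b, :, :, c] ** 2).sum() + 1e-12)
                      for c in range(C)])
        N = G / (G.mean() + eps)
        for c in range(C):
            out[b, :, :, c] = gain[c] * (x[b, :, :, c] * N[c]) + bias[c] \
                + x[b, :, :, c]
    return out


# ---------------------------------------------------------------------------
# stem
# ---------------------------------------------------------------------------

class TestStem:
    def test_quarters_resolution(self, rng):
        stem = Stem(16, rng)
        out = stem(Tensor(rng.random((2, 3, 64, 64))))
        assert out.shape == (2, 16, 16, 16)

    def test_rejects_indivisible_input(self, rng):
        stem = Stem(8, rng)
        with pytest.raises(ValueError, match="height 60"):
            stem(Tensor(np.zeros((1, 3, 60, 64))))
        with pytest.raises(ValueError, match="width 48"):
            stem(Tensor(np.zeros((1, 3, 64, 48))))

    def test_zero_image_zero_bias_gives_zero_features(self, rng):
        stem = Stem(8, rng)
        out = stem(Tensor(np.zeros((1, 3, 32, 32))))
        np.testing.assert_array_equal(out.data, 0.0)


# ---------------------------------------------------------------------------
# GRN
# ---------------------------------------------------------------------------

class TestGRN:
    def test_zero_gain_bias_is_identity(self, rng):
        x = Tensor(rng.standard_normal((2, 4, 4, 3)))
        out = grn(x, Tensor(np.zeros(3)), Tensor(np.zeros(3)))
        np.testing.assert_array_equal(out.data, x.data)

    def test_identical_channels_normalize_to_one(self, rng):
        base = rng.standard_normal((1, 3, 3, 1))
        x = Tensor(np.repeat(base, 4, axis=-1))
        out = grn(x, Tensor(np.ones(4)), Tensor(np.zeros(4)))
        np.testing.assert_allclose(out.data, 2 * x.data, atol=1e-5)

    def test_matches_two_pass_oracle(self, rng):
        x = rng.standard_normal((2, 2, 2, 3))
        gain, bias = rng.standard_normal(3), rng.standard_normal(3)
        out = grn(Tensor(x), Tensor(gain), Tensor(bias))
        np.testing.assert_allclose(out.data, loop_grn(x, gain, bias),
                                   atol=1e-6)

    def test_spatial_permutation_equivariance(self, rng):
        x = rng.standard_normal((1, 4, 4, 3))
        g = GRN(3)
        g.gain.data = rng.standard_normal(3)
        perm = rng.permutation(16)
        xp = x.reshape(1, 16, 3)[:, perm].reshape(1, 4, 4, 3)
        out = g(Tensor(x)).data.reshape(1, 16, 3)[:, perm]
        outp = g(Tensor(xp)).data.reshape(1, 16, 3)
        np.testing.assert_allclose(out, outp, atol=1e-12)


# ---------------------------------------------------------------------------
# ConvNeXt block
# ---------------------------------------------------------------------------

class TestConvNeXtBlock:
    def test_preserves_shape(self, rng):
        blk = ConvNeXtBlock(6, rng)
        x = Tensor(rng.standard_normal((2, 6, 8, 8)))
        assert blk(x).shape == x.shape

    def test_zero_final_projection_is_identity(self, rng):
        blk = ConvNeXtBlock(4, rng)
        blk.pw2.weight.data[:] = 0.0
        x = Tensor(rng.standard_normal((1, 4, 8, 8)))
        np.testing.assert_array_equal(blk(x).data, x.data)

    def test_expansion_round_trip_channels(self, rng):
        blk = ConvNeXtBlock(5, rng)
        assert blk.pw1.weight.shape == (5, 20)
        assert blk.pw2.weight.shape == (20, 5)

    def test_depthwise_conv_matches_loop_oracle(self, rng):
        x = rng.standard_normal((1, 1, 5, 5))
        w = rng.standard_normal((1, 1, 7, 7))
        out = ad.conv2d(Tensor(x), Tensor(w), None, padding=3, groups=1)
        np.testing.assert_allclose(out.data, loop_conv2d(x, w, padding=3),
                                   atol=1e-5)

    def test_multichannel_depthwise_matches_loop_oracle(self, rng):
        x = rng.standard_normal((2, 3, 6, 6))
        w = rng.standard_normal((3, 1, 7, 7))
        out = ad.conv2d(Tensor(x), Tensor(w), None, padding=3, groups=3)
        np.testing.assert_allclose(
            out.data, loop_conv2d(x, w, padding=3, groups=3), atol=1e-5)


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

class TestWindows:
    def test_window_count_and_size(self, rng):
        x = Tensor(rng.standard_normal((1, 3, 8, 8)))
        tokens = window_partition(x, 4)
        assert tokens.shape == (4, 16, 3)

    @pytest.mark.parametrize("shape,L", [((2, 3, 8, 8), 4), ((1, 5, 12, 8), 4),
                                         ((3, 2, 6, 6), 3), ((1, 1, 16, 16), 8)])
    def test_partition_merge_roundtrip_bit_exact(self, shape, L, rng):
        x = Tensor(rng.standard_normal(shape))
        merged = window_merge(window_partition(x, L), shape[2], shape[3])
        np.testing.assert_array_equal(merged.data, x.data)

    def test_window_zero_holds_topleft_block(self):
        x = Tensor(np.arange(16, dtype=float).reshape(1, 1, 4, 4))
        tokens = window_partition(x, 2)
        assert sorted(tokens.data[0, :, 0].tolist()) == [0.0, 1.0, 4.0, 5.0]
        # row-major token order within the window
        np.testing.assert_array_equal(tokens.data[0, :, 0], [0, 1, 4, 5])

    def test_rejects_indivisible(self, rng):
        with pytest.raises(ValueError, match="divisible"):
            window_partition(Tensor(np.zeros((1, 1, 6, 6))), 4)


# ---------------------------------------------------------------------------
# window MSA
# ---------------------------------------------------------------------------

class TestWindowMSA:
    def test_zero_values_give_zero_output(self, rng):
        msa = WindowMSA(4, 2, 2, rng)
        for lin in (msa.q, msa.k, msa.v, msa.o):
            lin.bias.data[:] = 0.0
        tokens = Tensor(np.zeros((3, 4, 4)))
        np.testing.assert_array_equal(msa(tokens).data, 0.0)

    def test_identity_projection_matches_closed_form(self, rng):
        """k=1 head, identity W's: softmax(X X^T / sqrt(C)) X."""
        msa = WindowMSA(2, 1, 2, rng)
        for lin in (msa.q, msa.k, msa.v, msa.o):
            lin.weight.data = np.eye(2)
            lin.bias.data[:] = 0.0
        X = np.array([[1.0, 0.5], [-0.3, 2.0], [0.0, 0.0], [1.5, -1.0]])
        out = msa(Tensor(X[None])).data[0]
        logits = X @ X.T / np.sqrt(2)
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        ref = (e / e.sum(axis=1, keepdims=True)) @ X
        np.testing.assert_allclose(out, ref, atol=1e-6)

    @pytest.mark.parametrize("L,C,k", [(2, 2, 1), (2, 4, 2), (4, 8, 2),
                                       (3, 6, 2)])
    def test_matches_bruteforce_oracle(self, L, C, k, rng):
        T = L * L
        msa = WindowMSA(C, k, L, rng)
        for lin in (msa.q, msa.k, msa.v, msa.o):
            lin.weight.data = rng.standard_normal((C, C)) * 0.5
            lin.bias.data = rng.standard_normal(C) * 0.1
        msa.pos.data = rng.standard_normal((T, C)) * 0.1
        tokens = rng.standard_normal((2, T, C))
        out = msa(Tensor(tokens)).data
        for n in range(2):
            ref = loop_attention(tokens[n], msa.q.weight.data,
                                 msa.k.weight.data, msa.v.weight.data,
                                 msa.o.weight.data, msa.q.bias.data,
                                 msa.k.bias.data, msa.v.bias.data,
                                 msa.o.bias.data, msa.pos.data, k)
            np.testing.assert_allclose(out[n], ref, atol=1e-5)

    def test_attention_rows_sum_to_one(self, rng):
        msa = WindowMSA(6, 3, 2, rng)
        weights = msa.attention_weights(Tensor(rng.standard_normal((5, 4, 6))))
        np.testing.assert_allclose(weights.sum(axis=-1), 1.0, atol=1e-6)

    def test_identical_tokens_get_identical_outputs(self, rng):
        msa = WindowMSA(4, 2, 2, rng)
        tokens = rng.standard_normal((1, 4, 4))
        tokens[0, 2] = tokens[0, 0]  # duplicate token
        msa.pos.data[:] = 0.0  # positional offset would break the symmetry
        out = msa(Tensor(tokens)).data
        np.testing.assert_allclose(out[0, 0], out[0, 2], atol=1e-12)


# ---------------------------------------------------------------------------
# transformer block
# ---------------------------------------------------------------------------

class TestTransformerBlock:
    def test_preserves_shape(self, rng):
        blk = TransformerBlock(8, 2, 4, rng)
        x = Tensor(rng.standard_normal((2, 8, 8, 8)))
        assert blk(x).shape == x.shape

    def test_cyclic_shift_roundtrip_is_identity(self, rng):
        x = Tensor(rng.standard_normal((1, 2, 8, 8)))
        out = ad.roll(ad.roll(x, (-2, -2), (2, 3)), (2, 2), (2, 3))
        np.testing.assert_array_equal(out.data, x.data)

    def test_zeroed_residual_paths_make_identity(self, rng):
        blk = TransformerBlock(4, 2, 4, rng)
        blk.attn.o.weight.data[:] = 0.0
        blk.attn.o.bias.data[:] = 0.0
        blk.attn.pos.data[:] = 0.0
        blk.ffn.pw2.weight.data[:] = 0.0
        x = Tensor(rng.standard_normal((1, 4, 8, 8)))
        np.testing.assert_array_equal(blk(x).data, x.data)

    def test_shifted_block_mixes_across_windows(self, rng):
        """A map constant per window but distinct across windows must change
        differently under a shifted block than an unshifted one."""
        plain = TransformerBlock(4, 1, 4, rng, shift=False)
        shifted = TransformerBlock(4, 1, 4, rng, shift=True)
        # same weights in both blocks
        shifted.load_state_dict(plain.state_dict())
        # each window carries a distinct channel direction (constant inside)
        dirs = np.array([[1.0, 0.2, -0.5, 0.0], [0.0, 1.0, 0.3, -0.2],
                         [-0.4, 0.0, 1.0, 0.6], [0.2, -0.3, 0.0, 1.0]])
        x = np.zeros((1, 4, 8, 8))
        for w, (r, c) in enumerate([(0, 0), (0, 1), (1, 0), (1, 1)]):
            x[0, :, 4 * r:4 * r + 4, 4 * c:4 * c + 4] = dirs[w][:, None, None]
        x = Tensor(x)
        out_plain, out_shift = plain(x).data, shifted(x).data
        assert not np.allclose(out_plain, out_shift, atol=1e-8)

    def test_shifted_mask_blocks_foreign_windows(self, rng):
        from octfluidseg.core_blocks import shifted_window_mask
        mask = shifted_window_mask(8, 8, 4, 2)
        assert mask.shape == (4, 16, 16)
        assert np.all(np.diagonal(mask, axis1=1, axis2=2) == 0)
        assert (mask < -1e8).any()


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

class TestResampling:
    @pytest.mark.parametrize("shape,out_shape", [
        ((1, 16, 8, 8), (1, 32, 4, 4)),
        ((2, 4, 6, 10), (2, 8, 3, 5)),
    ])
    def test_downsample_halves_space_doubles_channels(self, shape, out_shape,
                                                      rng):
        down = Downsample(shape[1], rng)
        assert down(Tensor(rng.standard_normal(shape))).shape == out_shape

    def test_downsample_rejects_odd_dims(self, rng):
        with pytest.raises(ValueError, match="odd"):
            Downsample(4, rng)(Tensor(np.zeros((1, 4, 5, 6))))

    def test_downsample_zero_input_zero_output(self, rng):
        down = Downsample(4, rng)
        out = down(Tensor(np.zeros((1, 4, 8, 8))))
        np.testing.assert_array_equal(out.data, 0.0)

    @pytest.mark.parametrize("shape,out_shape", [
        ((1, 32, 4, 4), (1, 16, 8, 8)),
        ((2, 8, 3, 5), (2, 4, 6, 10)),
    ])
    def test_upsample_doubles_space_halves_channels(self, shape, out_shape,
                                                    rng):
        up = Upsample(shape[1], rng)
        assert up(Tensor(rng.standard_normal(shape))).shape == out_shape

    def test_upsample_rejects_odd_channels(self, rng):
        with pytest.raises(ValueError, match="even"):
            Upsample(5, rng)

    def test_bilinear_preserves_constants(self):
        x = Tensor(np.full((1, 2, 4, 4), 3.7))
        out = ad.bilinear_resize(x, 8, 8)
        np.testing.assert_allclose(out.data, 3.7, atol=1e-12)
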