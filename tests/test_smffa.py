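"""Multi-scale skip fusion: projections, channel attention, full module.

The complete fusion pipeline (neighbor resampling, dual-kernel projections,
additive fusion, dual-pool channel attention, concatenation and reduction)
is validated against an independent loop/numpy oracle using the module's own
weights.
"""

import numpy as np
import pytest

from octfluidseg.autodiff import Tensor
from octfluidseg.smffa import (ChannelAttention, DualKernelProjection,
                               MultiScaleSkipFusion)
from test_core_blocks import loop_conv2d


def _bilinear_up2(x):
    """Independent 2x bilinear upsample (align_corners=False)."""
    B, C, H, W = x.shape
    out = np.zeros((B, C, 2 * H, 2 * W))
    for o in range(2 * H):
        sy = (o + 0.5) / 2 - 0.5
        y0 = int(np.clip(np.floor(sy), 0, H - 1))
        y1 = min(y0 + 1, H - 1)
        fy = np.clip(sy - np.floor(sy), 0, 1) if sy >= 0 else 0.0
        for p in range(2 * W):
            sx = (p + 0.5) / 2 - 0.5
            x0 = int(np.clip(np.floor(sx), 0, W - 1))
            x1 = min(x0 + 1, W - 1)
            fx = np.clip(sx - np.floor(sx), 0, 1) if sx >= 0 else 0.0
            out[:, :, o, p] = ((1 - fy) * (1 - fx) * x[:, :, y0, x0]
                               + (1 - fy) * fx * x[:, :, y0, x1]
                               + fy * (1 - fx) * x[:, :, y1, x0]
                               + fy * fx * x[:, :, y1, x1])
    return out


def _dual_oracle(proj, x):
    a = loop_conv2d(x, proj.k3.weight.data, proj.k3.bias.data, padding=1)
    b = loop_conv2d(x, proj.k5.weight.data, proj.k5.bias.data, padding=2)
    return np.concatenate([a, b], axis=1)


def _att_oracle(att, x):
    B, C = x.shape[:2]
    avg, mx = x.mean(axis=(2, 3)), x.max(axis=(2, 3))
    w1, w2 = att.w1.weight.data, att.w2.weight.data
    path = lambda s: np.maximum(s @ w1, 0.0) @ w2  # noqa: E731
    sig = 1 / (1 + np.exp(-(path(avg) + path(mx))))
    return x * sig.reshape(B, C, 1, 1)


def smffa_oracle(mod, f_i, f_tap, f_prev=None, f_next=None):
    fused = _dual_oracle(mod.proj_cur, f_i) + _dual_oracle(mod.proj_tap, f_tap)
    branches = []
    if f_prev is not None:
        p = loop_conv2d(f_prev, mod.down_prev.weight.data,
                        mod.down_prev.bias.data, stride=2, padding=0)
        branches.append(_att_oracle(mod.att_prev,
                                    fused + _dual_oracle(mod.proj_prev, p)))
    if f_next is not None:
        n = _bilinear_up2(f_next)
        branches.append(_att_oracle(mod.att_next,
                                    fused + _dual_oracle(mod.proj_next, n)))
    cat = branches[0] if len(branches) == 1 else np.concatenate(branches, 1)
    return loop_conv2d(cat, mod.out_conv.weight.data, mod.out_conv.bias.data,
                       padding=1)


def _randomize(mod, rng):
    for _, p in mod.named_parameters():
        p.data = rng.standard_normal(p.shape) * 0.3


class TestDualKernelProjection:
    def test_maps_any_input_channels_to_stage_channels(self, rng):
        for cin in (3, 8, 16):
            proj = DualKernelProjection(cin, 8, rng)
            out = proj(Tensor(rng.random((1, cin, 6, 6))))
            assert out.shape == (1, 8, 6, 6)

    def test_rejects_odd_output_channels(self, rng):
        with pytest.raises(ValueError, match="even"):
            DualKernelProjection(4, 5, rng)

    def test_zero_weights_give_zero_output(self, rng):
        proj = DualKernelProjection(3, 4, rng)
        for conv in (proj.k3, proj.k5):
            conv.weight.data[:] = 0.0
        out = proj(Tensor(rng.random((2, 3, 5, 5))))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_matches_loop_conv_oracle(self, rng):
        proj = DualKernelProjection(2, 4, rng)
        _randomize(proj, rng)
        x = rng.standard_normal((1, 2, 4, 4))
        np.testing.assert_allclose(proj(Tensor(x)).data,
                                   _dual_oracle(proj, x), atol=1e-6)


class TestChannelAttention:
    def test_zero_weights_force_half_attention(self, rng):
        att = ChannelAttention(8, rng)
        att.w1.weight.data[:] = 0.0
        att.w2.weight.data[:] = 0.0
        x = Tensor(rng.random((2, 8, 4, 4)))
        np.testing.assert_allclose(att(x).data, 0.5 * x.data, atol=1e-12)

    def test_weights_strictly_inside_unit_interval(self, rng):
        att = ChannelAttention(6, rng, reduction=2)
        w = att.weights(Tensor(rng.standard_normal((3, 6, 5, 5)))).data
        assert np.all((w > 0) & (w < 1))

    def test_gap_equals_gmp_on_constant_maps(self, rng):
        att = ChannelAttention(4, rng)
        x = Tensor(np.full((1, 4, 3, 3), 2.5))
        avg = x.mean(axis=(2, 3)).data
        mx = x.max(axis=(2, 3)).data
        np.testing.assert_array_equal(avg, mx)


class TestMultiScaleSkipFusion:
    def test_output_channels_equal_stage_channels_all_stages(self, rng):
        """Interior and boundary stages all emit C channels at stage size."""
        C0, H0 = 8, 16
        for i in range(4):
            C, H = C0 * 2 ** i, H0 // 2 ** i
            mod = MultiScaleSkipFusion(C, rng, has_prev=i > 0, has_next=i < 3,
                                       reduction=4)
            out = mod(Tensor(rng.random((1, C, H, H))),
                      Tensor(rng.random((1, C, H, H))),
                      f_prev=(Tensor(rng.random((1, C // 2, 2 * H, 2 * H)))
                              if i > 0 else None),
                      f_next=(Tensor(rng.random((1, 2 * C, H // 2, H // 2)))
                              if i < 3 else None))
            assert out.shape == (1, C, H, H)

    def test_boundary_stages_reject_foreign_neighbors(self, rng):
        first = MultiScaleSkipFusion(8, rng, has_prev=False, has_next=True)
        f = Tensor(rng.random((1, 8, 8, 8)))
        nxt = Tensor(rng.random((1, 16, 4, 4)))
        prv = Tensor(rng.random((1, 4, 16, 16)))
        with pytest.raises(ValueError, match="preceding"):
            first(f, f, f_prev=prv, f_next=nxt)
        last = MultiScaleSkipFusion(8, rng, has_prev=True, has_next=False)
        with pytest.raises(ValueError, match="succeeding"):
            last(f, f, f_prev=prv, f_next=nxt)

    def test_needs_at_least_one_neighbor(self, rng):
        with pytest.raises(ValueError, match="neighbor"):
            MultiScaleSkipFusion(8, rng, has_prev=False, has_next=False)

    def test_mismatched_tap_shape_rejected(self, rng):
        mod = MultiScaleSkipFusion(8, rng, has_prev=False, has_next=True)
        with pytest.raises(ValueError, match="tap"):
            mod(Tensor(np.zeros((1, 8, 8, 8))), Tensor(np.zeros((1, 8, 4, 4))),
                f_next=Tensor(np.zeros((1, 16, 4, 4))))

    def test_zero_attention_weights_halve_branch(self, rng):
        """W1 = W2 = 0 forces sigma(0) = 0.5 channel attention."""
        mod = MultiScaleSkipFusion(4, rng, has_prev=False, has_next=True,
                                   reduction=2)
        mod.att_next.w1.weight.data[:] = 0.0
        mod.att_next.w2.weight.data[:] = 0.0
        f = Tensor(rng.random((1, 4, 8, 8)))
        nxt = Tensor(rng.random((1, 8, 4, 4)))
        fused = (mod.proj_cur(f).data + mod.proj_tap(f).data
                 + _dual_oracle(mod.proj_next, _bilinear_up2(nxt.data)))
        expected_branch = 0.5 * fused
        got = mod(f, f, f_next=nxt).data
        ref = loop_conv2d(expected_branch, mod.out_conv.weight.data,
                          mod.out_conv.bias.data, padding=1)
        np.testing.assert_allclose(got, ref, atol=1e-6)

    def test_tap_equal_to_stage_doubles_projection(self, rng):
        """With shared projection weights and f_i == f_tap the fused current
        feature is exactly twice one projection."""
        mod = MultiScaleSkipFusion(4, rng, has_prev=False, has_next=True)
        mod.proj_tap.load_state_dict(mod.proj_cur.state_dict())
        f = rng.random((1, 4, 8, 8))
        one = mod.proj_cur(Tensor(f)).data
        fused = mod.proj_cur(Tensor(f)).data + mod.proj_tap(Tensor(f)).data
        np.testing.assert_allclose(fused, 2 * one, atol=1e-12)

    @pytest.mark.parametrize("stage", ["first", "interior", "last"])
    def test_matches_end_to_end_loop_oracle(self, stage, rng):
        C, H = 4, 8
        has_prev, has_next = stage != "first", stage != "last"
        mod = MultiScaleSkipFusion(C, rng, has_prev=has_prev,
                                   has_next=has_next, reduction=2)
        _randomize(mod, rng)
        f_i = rng.standard_normal((1, C, H, H))
        f_tap = rng.standard_normal((1, C, H, H))
        f_prev = rng.standard_normal((1, C // 2, 2 * H, 2 * H)) if has_prev \
            else None
        f_next = rng.standard_normal((1, 2 * C, H // 2, H // 2)) if has_next \
            else None
        got = mod(Tensor(f_i), Tensor(f_tap),
                  f_prev=None if f_prev is None else Tensor(f_prev),
                  f_next=None if f_next is None else Tensor(f_next)).data
        ref = smffa_oracle(mod, f_i, f_tap, f_prev, f_next)
        np.testing.assert_allclose(got, ref, atol=1e-5)
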