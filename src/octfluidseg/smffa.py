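"""Self-adaptive multi-scale feature fusion attention (SMFFA) skip connections.

Each encoder stage i contributes two features to its skip: the stage output
F_i and a tap F_i_next taken right after the stage's ConvNeXt blocks (before
the Transformer blocks).  Neighbor-stage features are resampled to stage-i
resolution — the preceding (higher-resolution) stage with a 2x2 stride-2
convolution, the succeeding (lower-resolution) stage with 2x bilinear
upsampling.  Every feature then passes a dual-kernel projection (parallel
3x3 and 5x5 convolutions, each emitting C/2 channels of the current stage,
concatenated to C), the current-stage pair is added, the sum is added to
each resampled neighbor, each of those fused maps is re-weighted by a
dual-pool (GAP + GMP) channel attention, and the attended branches are
concatenated and reduced back to C channels by a 3x3 convolution.

Boundary stages (first and last) have a single neighbor; their lone attended
branch feeds the final convolution alone.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Conv2d, Linear, Module, Tensor, bilinear_resize

__all__ = ["DualKernelProjection", "ChannelAttention", "MultiScaleSkipFusion"]


class DualKernelProjection(Module):
    """Parallel 3x3 and 5x5 convolutions, each C_in -> C/2, concatenated to C."""

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator):
        if out_channels % 2:
            raise ValueError(f"stage channel count {out_channels} must be even")
        half = out_channels // 2
        self.k3 = Conv2d(in_channels, half, 3, rng, padding=1)
        self.k5 = Conv2d(in_channels, half, 5, rng, padding=2)

    def forward(self, x: Tensor) -> Tensor:
        return ad.concat([self.k3(x), self.k5(x)], axis=1)


class ChannelAttention(Module):
    """Squeeze-excitation-style dual-pool channel attention.

    GAP and GMP summaries each pass the shared bottleneck W2·ReLU(W1·s); the
    two paths are summed and squashed with a sigmoid to per-channel weights
    in (0, 1), which re-scale the input map.
    """

    def __init__(self, channels: int, rng: np.random.Generator,
                 reduction: int = 16):
        hidden = max(1, channels // reduction)
        self.w1 = Linear(channels, hidden, rng, bias=False)
        self.w2 = Linear(hidden, channels, rng, bias=False)

    def weights(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=(2, 3))
        mx = x.max(axis=(2, 3))
        path = lambda s: self.w2(ad.relu(self.w1(s)))  # noqa: E731
        return ad.sigmoid(ad.add(path(avg), path(mx)))

    def forward(self, x: Tensor) -> Tensor:
        B, C = x.shape[:2]
        return ad.mul(x, ad.reshape(self.weights(x), (B, C, 1, 1)))


class MultiScaleSkipFusion(Module):
    """SMFFA for one encoder stage.

    Parameters
    ----------
    channels: stage channel count C (the fused output always has C channels).
    has_prev / has_next: whether a preceding (C/2 channels, 2x resolution) or
        succeeding (2C channels, half resolution) stage exists.
    reduction: channel-attention bottleneck ratio.
    """

    def __init__(self, channels: int, rng: np.random.Generator,
                 has_prev: bool, has_next: bool, reduction: int = 16):
        if not (has_prev or has_next):
            raise ValueError("a stage must have at least one neighbor")
        C = channels
        self.has_prev, self.has_next = has_prev, has_next
        self.proj_cur = DualKernelProjection(C, C, rng)
        self.proj_tap = DualKernelProjection(C, C, rng)
        n_branches = 0
        if has_prev:
            # 2x2 stride-2 downsampling conv preserves its input channel count
            self.down_prev = Conv2d(C // 2, C // 2, 2, rng, stride=2)
            self.proj_prev = DualKernelProjection(C // 2, C, rng)
            self.att_prev = ChannelAttention(C, rng, reduction)
            n_branches += 1
        if has_next:
            self.proj_next = DualKernelProjection(2 * C, C, rng)
            self.att_next = ChannelAttention(C, rng, reduction)
            n_branches += 1
        self.out_conv = Conv2d(n_branches * C, C, 3, rng, padding=1)

    def forward(self, f_i: Tensor, f_i_next: Tensor,
                f_prev: Tensor | None = None,
                f_next: Tensor | None = None) -> Tensor:
        if self.has_prev != (f_prev is not None):
            raise ValueError("preceding-stage feature presence mismatch")
        if self.has_next != (f_next is not None):
            raise ValueError("succeeding-stage feature presence mismatch")
        if f_i.shape != f_i_next.shape:
            raise ValueError(
                f"stage feature and ConvNeXt tap differ: {f_i.shape} vs "
                f"{f_i_next.shape}")
        H, W = f_i.shape[2:]
        fused = ad.add(self.proj_cur(f_i), self.proj_tap(f_i_next))
        branches: list[Tensor] = []
        if f_prev is not None:
            if f_prev.shape[2] != 2 * H or f_prev.shape[3] != 2 * W:
                raise ValueError(
                    f"preceding feature must be 2x resolution, got "
                    f"{f_prev.shape[2:]} for stage {(H, W)}")
            p = self.proj_prev(self.down_prev(f_prev))
            branches.append(self.att_prev(ad.add(fused, p)))
        if f_next is not None:
            if 2 * f_next.shape[2] != H or 2 * f_next.shape[3] != W:
                raise ValueError(
                    f"succeeding feature must be half resolution, got "
                    f"{f_next.shape[2:]} for stage {(H, W)}")
            n = self.proj_next(bilinear_resize(f_next, H, W))
            branches.append(self.att_next(ad.add(fused, n)))
        return self.out_conv(branches[0] if len(branches) == 1
                             else ad.concat(branches, axis=1))
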