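"""Shared neural building blocks of the hybrid encoder/decoder.

Contains the patchify stem, the ConvNeXt-V2 residual block with global
response normalization (GRN), window partition/merge utilities, window-based
multi-head self-attention (WMSA) with optional cyclic shift and cross-window
masking, the Transformer block, and the inter-stage down/up-sampling layers.

Feature maps are NCHW float tensors throughout.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import (Conv2d, LayerNorm, Linear, Module, Tensor,
                       bilinear_resize)

__all__ = [
    "Stem",
    "grn",
    "GRN",
    "ConvNeXtBlock",
    "window_partition",
    "window_merge",
    "WindowMSA",
    "shifted_window_mask",
    "TransformerBlock",
    "Downsample",
    "Upsample",
]


# ---------------------------------------------------------------------------
# stem
# ---------------------------------------------------------------------------

class Stem(Module):
    """4x4, stride-4 patchify convolution (3 -> C0) followed by LayerNorm.

    Quarters the spatial resolution, so a divisible-by-32 input guarantees
    that every later stage and attention window tiles exactly.
    """

    def __init__(self, out_channels: int, rng: np.random.Generator,
                 in_channels: int = 3):
        self.conv = Conv2d(in_channels, out_channels, 4, rng, stride=4)
        self.norm = LayerNorm(out_channels)

    def forward(self, x: Tensor) -> Tensor:
        _, _, H, W = x.shape
        for name, dim in (("height", H), ("width", W)):
            if dim % 32:
                raise ValueError(
                    f"input {name} {dim} is not divisible by 32; pad or resize")
        return self.norm(self.conv(x))


# ---------------------------------------------------------------------------
# global response normalization (ConvNeXt-V2)
# ---------------------------------------------------------------------------

def grn(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-6) -> Tensor:
    """Global response normalization on a channels-last (B, H, W, C) tensor.

    Per channel c: G(x)_c = ||x_c||_2 over the spatial grid;
    N(x)_c = G(x)_c / (mean_c G(x) + eps); output = gain * (x * N(x)) + bias + x.
    With zero gain and bias this is the identity (residual formulation).
    """
    # tiny constant inside the root keeps the gradient finite at x == 0
    g = ad.sqrt(ad.reduce_sum(ad.mul(x, x), axis=(1, 2), keepdims=True) + 1e-12)
    n = ad.mul(g, ad.power(ad.reduce_mean(g, axis=-1, keepdims=True) + eps, -1.0))
    return ad.add(ad.add(ad.mul(gain, ad.mul(x, n)), bias), x)


class GRN(Module):
    """Learnable GRN with per-channel gain/bias, both zero-initialized."""

    def __init__(self, channels: int):
        self.gain = Tensor(np.zeros(channels), requires_grad=True)
        self.bias = Tensor(np.zeros(channels), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return grn(x, self.gain, self.bias)


# ---------------------------------------------------------------------------
# ConvNeXt-V2 block
# ---------------------------------------------------------------------------

class ConvNeXtBlock(Module):
    """Depthwise 7x7 -> LN -> 1x1 (C -> 4C) -> GELU -> GRN -> 1x1 (4C -> C) + skip.

    The pointwise convolutions run channels-last as linear layers, the
    ConvNeXt convention; the expansion ratio is fixed at 4.
    """

    EXPANSION = 4

    def __init__(self, channels: int, rng: np.random.Generator):
        self.dwconv = Conv2d(channels, channels, 7, rng, padding=3,
                             groups=channels)
        self.norm = LayerNorm(channels)
        self.pw1 = Linear(channels, self.EXPANSION * channels, rng)
        self.grn = GRN(self.EXPANSION * channels)
        self.pw2 = Linear(self.EXPANSION * channels, channels, rng)

    def forward(self, x: Tensor) -> Tensor:
        h = self.dwconv(x)
        h = self.norm(h)
        h = ad.transpose(h, (0, 2, 3, 1))  # NCHW -> NHWC
        h = self.pw1(h)
        h = ad.gelu(h)
        h = self.grn(h)
        h = self.pw2(h)
        h = ad.transpose(h, (0, 3, 1, 2))
        return ad.add(h, x)


# ---------------------------------------------------------------------------
# window partition / merge
# ---------------------------------------------------------------------------

def window_partition(x: Tensor, window: int) -> Tensor:
    """Split an NCHW map into non-overlapping LxL windows of flattened tokens.

    Returns (B * num_windows, L^2, C); windows are enumerated row-major over
    the window grid and tokens row-major within each window, so the merge
    below is its bit-exact inverse.
    """
    B, C, H, W = x.shape
    if H % window or W % window:
        raise ValueError(f"spatial dims ({H}, {W}) not divisible by window {window}")
    nh, nw = H // window, W // window
    t = ad.transpose(x, (0, 2, 3, 1))                       # B H W C
    t = ad.reshape(t, (B, nh, window, nw, window, C))
    t = ad.transpose(t, (0, 1, 3, 2, 4, 5))                 # B nh nw L L C
    return ad.reshape(t, (B * nh * nw, window * window, C))


def window_merge(tokens: Tensor, H: int, W: int) -> Tensor:
    """Inverse of :func:`window_partition` back to an NCHW map."""
    N, T, C = tokens.shape
    window = int(round(T ** 0.5))
    if window * window != T:
        raise ValueError(f"token count {T} is not a square window")
    nh, nw = H // window, W // window
    B = N // (nh * nw)
    t = ad.reshape(tokens, (B, nh, nw, window, window, C))
    t = ad.transpose(t, (0, 1, 3, 2, 4, 5))
    t = ad.reshape(t, (B, H, W, C))
    return ad.transpose(t, (0, 3, 1, 2))


# ---------------------------------------------------------------------------
# window-based multi-head self-attention
# ---------------------------------------------------------------------------

class WindowMSA(Module):
    """Multi-head self-attention within each window.

    Tokens of every window are projected to Q/K/V (CxC matrices), split into
    ``heads`` heads of dimension C/heads, attended with scaled dot-product
    softmax, concatenated, output-projected, and offset by a learnable
    positional table B of shape (L^2, C) added after the output projection.
    """

    def __init__(self, channels: int, heads: int, window: int,
                 rng: np.random.Generator):
        if channels % heads:
            raise ValueError(f"channels {channels} not divisible by heads {heads}")
        self.heads = heads
        self.window = window
        self.q = Linear(channels, channels, rng)
        self.k = Linear(channels, channels, rng)
        self.v = Linear(channels, channels, rng)
        self.o = Linear(channels, channels, rng)
        self.pos = Tensor(np.zeros((window * window, channels)),
                          requires_grad=True)

    def attention_weights(self, tokens: Tensor,
                          mask: np.ndarray | None = None) -> np.ndarray:
        """Post-softmax attention weights (N, heads, T, T), for inspection."""
        _, w = self._attend(tokens, mask, keep_weights=True)
        return w

    def _attend(self, tokens: Tensor, mask: np.ndarray | None,
                keep_weights: bool = False):
        N, T, C = tokens.shape
        k = self.heads
        dk = C // k

        def split_heads(t: Tensor) -> Tensor:
            t = ad.reshape(t, (N, T, k, dk))
            return ad.transpose(t, (0, 2, 1, 3))            # N k T dk

        Q = split_heads(self.q(tokens))
        K = split_heads(self.k(tokens))
        V = split_heads(self.v(tokens))
        logits = ad.mul(ad.matmul(Q, ad.transpose(K, (0, 1, 3, 2))),
                        1.0 / np.sqrt(dk))
        if mask is not None:
            nw = mask.shape[0]
            logits = ad.reshape(logits, (N // nw, nw, k, T, T))
            logits = ad.add(logits, mask[None, :, None, :, :])
            logits = ad.reshape(logits, (N, k, T, T))
        attn = ad.softmax(logits, axis=-1)
        out = ad.matmul(attn, V)
        out = ad.transpose(out, (0, 2, 1, 3))
        out = ad.reshape(out, (N, T, C))
        out = ad.add(self.o(out), self.pos)
        return out, (attn.data if keep_weights else None)

    def forward(self, tokens: Tensor, mask: np.ndarray | None = None) -> Tensor:
        out, _ = self._attend(tokens, mask)
        return out


def shifted_window_mask(H: int, W: int, window: int, shift: int) -> np.ndarray:
    """Cross-window attention mask for a cyclically shifted map.

    Labels the shifted canvas with region ids; token pairs from different
    pre-shift windows get a large negative logit offset. Shape
    (num_windows, L^2, L^2).
    """
    img = np.zeros((H, W))
    cnt = 0
    for hs in (slice(0, -window), slice(-window, -shift), slice(-shift, None)):
        for ws in (slice(0, -window), slice(-window, -shift), slice(-shift, None)):
            img[hs, ws] = cnt
            cnt += 1
    nh, nw = H // window, W // window
    wins = img.reshape(nh, window, nw, window).transpose(0, 2, 1, 3)
    wins = wins.reshape(nh * nw, window * window)
    diff = wins[:, :, None] - wins[:, None, :]
    return np.where(diff != 0, -1e9, 0.0)


# ---------------------------------------------------------------------------
# Transformer block
# ---------------------------------------------------------------------------

class FeedForward(Module):
    """1x1 conv (C -> 4C) -> GELU -> depthwise 3x3 -> GELU -> 1x1 conv (4C -> C)."""

    def __init__(self, channels: int, rng: np.random.Generator,
                 expansion: int = 4):
        hidden = expansion * channels
        self.pw1 = Conv2d(channels, hidden, 1, rng)
        self.dw = Conv2d(hidden, hidden, 3, rng, padding=1, groups=hidden)
        self.pw2 = Conv2d(hidden, channels, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.pw2(ad.gelu(self.dw(ad.gelu(self.pw1(x)))))


class TransformerBlock(Module):
    """Pre-norm windowed attention block: x + WMSA(LN(x)), then x + FFN(LN(x)).

    With ``shift`` the map is cyclically rolled by floor(L/2) before window
    partition and rolled back after merge, with cross-window token pairs
    masked out — the alternating shifted-window scheme that lets information
    travel between windows across consecutive blocks.
    """

    def __init__(self, channels: int, heads: int, window: int,
                 rng: np.random.Generator, shift: bool = False):
        self.window = window
        self.shift = window // 2 if shift else 0
        self.norm1 = LayerNorm(channels)
        self.attn = WindowMSA(channels, heads, window, rng)
        self.norm2 = LayerNorm(channels)
        self.ffn = FeedForward(channels, rng)
        self._mask_cache: dict[tuple[int, int], np.ndarray] = {}

    def _mask(self, H: int, W: int) -> np.ndarray | None:
        if not self.shift:
            return None
        key = (H, W)
        if key not in self._mask_cache:
            self._mask_cache[key] = shifted_window_mask(H, W, self.window,
                                                        self.shift)
        return self._mask_cache[key]

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        h = self.norm1(x)
        if self.shift:
            h = ad.roll(h, (-self.shift, -self.shift), (2, 3))
        tokens = window_partition(h, self.window)
        tokens = self.attn(tokens, self._mask(H, W))
        h = window_merge(tokens, H, W)
        if self.shift:
            h = ad.roll(h, (self.shift, self.shift), (2, 3))
        x = ad.add(h, x)
        return ad.add(self.ffn(self.norm2(x)), x)


# ---------------------------------------------------------------------------
# stage resampling
# ---------------------------------------------------------------------------

class Downsample(Module):
    """LayerNorm then 2x2 stride-2 convolution: halves H/W, doubles C."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.norm = LayerNorm(channels)
        self.conv = Conv2d(channels, 2 * channels, 2, rng, stride=2)

    def forward(self, x: Tensor) -> Tensor:
        _, _, H, W = x.shape
        if H % 2 or W % 2:
            raise ValueError(f"cannot halve odd spatial dims ({H}, {W})")
        return self.conv(self.norm(x))


class Upsample(Module):
    """2x bilinear interpolation then 3x3 convolution: doubles H/W, halves C."""

    def __init__(self, channels: int, rng: np.random.Generator):
        if channels % 2:
            raise ValueError(f"channel count {channels} must be even to halve")
        self.conv = Conv2d(channels, channels // 2, 3, rng, padding=1)

    def forward(self, x: Tensor) -> Tensor:
        _, _, H, W = x.shape
        return self.conv(bilinear_resize(x, 2 * H, 2 * W))
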