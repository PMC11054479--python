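"""Region-aware spatial attention (RASA).

Retinal fluid lesions sit predominantly in the central rows of a B-scan.
RASA encodes that location prior: the feature map is split into four equal
horizontal bands (top-down), each band gets a multi-kernel spatial-attention
map computed from its channel-wise mean/max pool, the four band maps are
re-assembled along the height axis, normalized with a softmax so the bands
compete for weight, and the result re-weights the input elementwise
(broadcast over channels).
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Conv2d, Module, Tensor

__all__ = ["split_bands", "RegionAwareSpatialAttention"]

N_BANDS = 4  # fixed: four equal horizontal regions


def split_bands(x: Tensor) -> list[Tensor]:
    """Split an NCHW map into four equal-height bands, top-down.

    Concatenating the result along the height axis reconstructs the input
    bit-exactly.
    """
    H = x.shape[2]
    if H % N_BANDS:
        raise ValueError(f"height {H} not divisible by {N_BANDS} bands")
    h = H // N_BANDS
    return [x[:, :, i * h:(i + 1) * h, :] for i in range(N_BANDS)]


class RegionAwareSpatialAttention(Module):
    """Four-band spatial attention with 1/3/5/7 multi-kernel fusion.

    One shared attention head is applied to every band: channel mean and max
    are concatenated to a 2-channel map, passed through four parallel
    same-padded convolutions (1x1, 3x3, 5x5, 7x7, each 2 -> 1 channel),
    concatenated, reduced 4 -> 1 by a 7x7 convolution, and squashed with a
    sigmoid.  Band maps are then stacked along height and softmax-normalized.

    Parameters
    ----------
    softmax_axis:
        ``"height"`` (default) normalizes each image column over the full
        height, weighting the four regions against each other at every
        lateral position; ``"hw-flat"`` normalizes over all spatial
        positions jointly.
    """

    def __init__(self, rng: np.random.Generator, softmax_axis: str = "height"):
        if softmax_axis not in ("height", "hw-flat"):
            raise ValueError(f"unknown softmax axis {softmax_axis!r}")
        self.softmax_axis = softmax_axis
        self.branches = [Conv2d(2, 1, k, rng, padding=k // 2)
                         for k in (1, 3, 5, 7)]
        self.fuse = Conv2d(4, 1, 7, rng, padding=3)

    def band_logits(self, band: Tensor) -> Tensor:
        """Per-band sigmoid attention map (B, 1, H/4, W), entries in (0, 1)."""
        pooled = ad.concat([band.mean(axis=1, keepdims=True),
                            band.max(axis=1, keepdims=True)], axis=1)
        multi = ad.concat([conv(pooled) for conv in self.branches], axis=1)
        return ad.sigmoid(self.fuse(multi))

    def attention_map(self, x: Tensor) -> Tensor:
        """Softmax-normalized spatial attention map S_s of shape (B, 1, H, W).

        Maps too short to carry four bands (H < 4, reached only by heavily
        scaled-down configurations) are treated as a single band.
        """
        if x.shape[2] % N_BANDS == 0:
            logits = ad.concat([self.band_logits(b) for b in split_bands(x)],
                               axis=2)
        else:
            logits = self.band_logits(x)
        if self.softmax_axis == "height":
            return ad.softmax(logits, axis=2)
        B, _, H, W = logits.shape
        flat = ad.reshape(logits, (B, 1, H * W))
        return ad.reshape(ad.softmax(flat, axis=-1), (B, 1, H, W))

    def forward(self, x: Tensor) -> Tensor:
        return ad.mul(self.attention_map(x), x)
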