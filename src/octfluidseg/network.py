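"""The full U-shaped hybrid segmentation network.

Topology: patchify stem -> four encoder stages (ConvNeXt blocks, then
shifted-window Transformer blocks, then region-aware spatial attention) with
a downsampling layer between stages -> three-ConvNeXt-block bottleneck ->
four decoder stages of Transformer blocks fed by multi-scale fused skip
connections -> 4x bilinear recovery and a 1x1 classifier head.

Stage i (i = 0..3) runs at resolution H/2^(i+2) x W/2^(i+2) with 2^i * C0
channels; the defaults (C0=96, heads 3/6/12/24, 8x8 windows, 3 ConvNeXt + 2
Transformer blocks per encoder stage, 2 Transformer blocks per decoder
stage) give the full-size model for 512x512 inputs.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import autodiff as ad
from .autodiff import Conv2d, Module, ModuleList, Tensor, bilinear_resize
from .core_blocks import (ConvNeXtBlock, Downsample, Stem, TransformerBlock,
                          Upsample)
from .rasa import RegionAwareSpatialAttention
from .smffa import MultiScaleSkipFusion

__all__ = ["ModelConfig", "StageFeatures", "SegmentationModel", "build_model",
           "save_checkpoint", "load_checkpoint"]

N_STAGES = 4


@dataclass
class ModelConfig:
    """All architectural constants, with the full-size defaults."""

    base_channels: int = 96
    heads: tuple[int, ...] = (3, 6, 12, 24)
    window: int = 8
    convnext_blocks_per_stage: int = 3
    transformer_blocks_per_stage: int = 2
    bottleneck_blocks: int = 3
    decoder_blocks_per_stage: int = 2
    num_classes: int = 4
    input_size: int = 512
    rasa_softmax_axis: str = "height"
    smffa_reduction: int = 16
    seed: int = 0
    # ablation switches
    use_rasa: bool = True
    use_smffa: bool = True
    encoder_use_convnext: bool = True
    encoder_use_transformer: bool = True
    decoder_type: str = "transformer"
    head_after_upsample: bool = True

    @property
    def stage_channels(self) -> tuple[int, ...]:
        return tuple(self.base_channels * 2 ** i for i in range(N_STAGES))

    def stage_resolution(self, i: int) -> int:
        return self.input_size // 2 ** (i + 2)

    def stage_window(self, i: int) -> int:
        """Attention window at stage i, clamped to the stage resolution."""
        return min(self.window, self.stage_resolution(i))

    def validate(self) -> None:
        if len(self.heads) != N_STAGES:
            raise ValueError(f"need {N_STAGES} head counts, got {self.heads}")
        for i, (c, h) in enumerate(zip(self.stage_channels, self.heads)):
            if c % h:
                raise ValueError(
                    f"stage {i}: channels {c} not divisible by heads {h}")
        if self.input_size % 32:
            raise ValueError(f"input_size {self.input_size} not divisible by 32")
        if self.input_size % (4 * self.window):
            raise ValueError(
                f"input_size {self.input_size} not divisible by 4*window "
                f"({4 * self.window})")
        for i in range(N_STAGES):
            res, win = self.stage_resolution(i), self.stage_window(i)
            if res % win:
                raise ValueError(
                    f"stage {i} resolution {res} not divisible by window {win}")
        if self.rasa_softmax_axis not in ("height", "hw-flat"):
            raise ValueError(f"bad rasa_softmax_axis {self.rasa_softmax_axis!r}")
        if self.decoder_type not in ("transformer", "convnext"):
            raise ValueError(f"bad decoder_type {self.decoder_type!r}")
        if not (self.encoder_use_convnext or self.encoder_use_transformer):
            raise ValueError("encoder needs at least one block family")
        if self.stage_resolution(0) % 4:
            raise ValueError("stage-0 resolution must allow 4 attention bands")

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["heads"] = list(self.heads)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelConfig":
        d = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(d) - known
        if extra:
            raise ValueError(f"unknown model config keys: {sorted(extra)}")
        if "heads" in d:
            d["heads"] = tuple(d["heads"])
        return cls(**d)


@dataclass
class StageFeatures:
    """Skip-connection bundle of one encoder stage."""

    f: Tensor        # stage output (after Transformer blocks and RASA)
    f_next: Tensor   # tap right after the stage's ConvNeXt blocks


class EncoderStage(Module):
    def __init__(self, cfg: ModelConfig, i: int, rng: np.random.Generator):
        C, heads = cfg.stage_channels[i], cfg.heads[i]
        win, res = cfg.stage_window(i), cfg.stage_resolution(i)
        self.convnext = ModuleList(
            [ConvNeXtBlock(C, rng) for _ in range(cfg.convnext_blocks_per_stage)]
            if cfg.encoder_use_convnext else [])
        self.transformer = ModuleList(
            [TransformerBlock(C, heads, win, rng,
                              shift=(b % 2 == 1 and win < res))
             for b in range(cfg.transformer_blocks_per_stage)]
            if cfg.encoder_use_transformer else [])
        self.rasa = (RegionAwareSpatialAttention(rng, cfg.rasa_softmax_axis)
                     if cfg.use_rasa else None)

    def forward(self, x: Tensor) -> StageFeatures:
        for blk in self.convnext:
            x = blk(x)
        tap = x
        for blk in self.transformer:
            x = blk(x)
        if self.rasa is not None:
            x = self.rasa(x)
        return StageFeatures(f=x, f_next=tap)


class DecoderStage(Module):
    def __init__(self, cfg: ModelConfig, i: int, rng: np.random.Generator,
                 has_skip: bool):
        C, heads = cfg.stage_channels[i], cfg.heads[i]
        win, res = cfg.stage_window(i), cfg.stage_resolution(i)
        self.fuse = Conv2d(2 * C, C, 1, rng) if has_skip else None
        if cfg.decoder_type == "transformer":
            blocks = [TransformerBlock(C, heads, win, rng,
                                       shift=(b % 2 == 1 and win < res))
                      for b in range(cfg.decoder_blocks_per_stage)]
        else:
            blocks = [ConvNeXtBlock(C, rng)
                      for _ in range(cfg.decoder_blocks_per_stage)]
        self.blocks = ModuleList(blocks)

    def forward(self, x: Tensor, skip: Tensor | None) -> Tensor:
        if (skip is None) != (self.fuse is None):
            raise ValueError("skip presence does not match decoder stage wiring")
        if skip is not None:
            x = self.fuse(ad.concat([x, skip], axis=1))
        for blk in self.blocks:
            x = blk(x)
        return x


class SegmentationModel(Module):
    """Encoder/bottleneck/decoder assembly; see the module docstring."""

    def __init__(self, cfg: ModelConfig):
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        C = cfg.stage_channels
        self.stem = Stem(C[0], rng)
        self.encoder = ModuleList([EncoderStage(cfg, i, rng)
                                   for i in range(N_STAGES)])
        self.downsamples = ModuleList([Downsample(C[i], rng)
                                       for i in range(N_STAGES - 1)])
        self.bottleneck = ModuleList([ConvNeXtBlock(C[-1], rng)
                                      for _ in range(cfg.bottleneck_blocks)])
        if cfg.use_smffa:
            self.smffa = ModuleList([
                MultiScaleSkipFusion(C[i], rng,
                                     has_prev=(i > 0),
                                     has_next=(i < N_STAGES - 1),
                                     reduction=cfg.smffa_reduction)
                for i in range(N_STAGES)])
        else:
            self.smffa = None
        self.decoder = ModuleList([DecoderStage(cfg, i, rng, has_skip=True)
                                   for i in range(N_STAGES)])
        self.upsamples = ModuleList([Upsample(C[i], rng)
                                     for i in range(1, N_STAGES)])
        self.head = Conv2d(C[0], cfg.num_classes, 1, rng)

    # -- encoder ----------------------------------------------------------
    def encode_with_taps(self, image: Tensor) -> list[StageFeatures]:
        """Run stem + encoder, returning each stage's (output, ConvNeXt tap)."""
        x = self.stem(image)
        bundles: list[StageFeatures] = []
        for i, stage in enumerate(self.encoder):
            sf = stage(x)
            bundles.append(sf)
            x = self.downsamples[i](sf.f) if i < N_STAGES - 1 else sf.f
        return bundles

    def _skips(self, bundles: list[StageFeatures]) -> list[Tensor]:
        if self.smffa is None:
            return [b.f for b in bundles]
        skips = []
        for i in range(N_STAGES):
            skips.append(self.smffa[i](
                bundles[i].f, bundles[i].f_next,
                f_prev=bundles[i - 1].f if i > 0 else None,
                f_next=bundles[i + 1].f if i < N_STAGES - 1 else None))
        return skips

    def forward(self, image: Tensor) -> Tensor:
        S = self.cfg.input_size
        if image.shape[-2:] != (S, S):
            raise ValueError(
                f"expected {S}x{S} input, got {image.shape[-2]}x{image.shape[-1]}")
        bundles = self.encode_with_taps(image)
        skips = self._skips(bundles)
        x = bundles[-1].f
        for blk in self.bottleneck:
            x = blk(x)
        for i in range(N_STAGES - 1, -1, -1):
            x = self.decoder[i](x, skips[i])
            if i > 0:
                x = self.upsamples[i - 1](x)
        if self.cfg.head_after_upsample:
            x = bilinear_resize(x, S, S)
            return self.head(x)
        x = self.head(x)
        return bilinear_resize(x, S, S)

    def predict(self, image: Tensor) -> np.ndarray:
        """Argmax class mask (B, H, W) without recording gradients."""
        with ad.no_grad():
            logits = self.forward(image)
        return logits.data.argmax(axis=1)

    # -- introspection ----------------------------------------------------
    def census(self) -> dict:
        """Structural counts used by the build-time architecture audit."""
        cfg = self.cfg
        return {
            "stage_channels": list(cfg.stage_channels),
            "stage_resolutions": [cfg.stage_resolution(i) for i in range(N_STAGES)],
            "heads": list(cfg.heads),
            "windows": [cfg.stage_window(i) for i in range(N_STAGES)],
            "encoder_convnext_blocks": [len(s.convnext) for s in self.encoder],
            "encoder_transformer_blocks": [len(s.transformer) for s in self.encoder],
            "rasa_modules": sum(s.rasa is not None for s in self.encoder),
            "smffa_modules": 0 if self.smffa is None else len(self.smffa),
            "bottleneck_blocks": len(self.bottleneck),
            "decoder_blocks": [len(d.blocks) for d in self.decoder],
            "decoder_type": cfg.decoder_type,
            "downsamples": len(self.downsamples),
            "upsamples": len(self.upsamples),
            "n_parameters": int(sum(p.data.size for p in self.parameters())),
        }

    def describe(self) -> str:
        """Human-readable per-stage shape log emitted at build time."""
        cfg, out = self.cfg, io.StringIO()
        print(f"input {cfg.input_size}x{cfg.input_size}x3", file=out)
        for i in range(N_STAGES):
            r = cfg.stage_resolution(i)
            print(f"stage {i}: {r}x{r}x{cfg.stage_channels[i]} "
                  f"heads={cfg.heads[i]} window={cfg.stage_window(i)}",
                  file=out)
        print(f"bottleneck: {cfg.stage_resolution(3)}x{cfg.stage_resolution(3)}"
              f"x{cfg.stage_channels[3]} ({cfg.bottleneck_blocks} blocks)",
              file=out)
        print(f"head: {cfg.num_classes} classes at {cfg.input_size}"
              f"x{cfg.input_size}", file=out)
        return out.getvalue()


def build_model(cfg: ModelConfig | None = None) -> SegmentationModel:
    """Validate the config and construct the model (random init, seeded)."""
    return SegmentationModel(cfg or ModelConfig())


# ---------------------------------------------------------------------------
# checkpoints (npz with the YAML config embedded)
# ---------------------------------------------------------------------------

def save_checkpoint(model: SegmentationModel, path, extra: dict | None = None) -> None:
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    arrays["config_yaml"] = np.array(model.cfg.to_yaml())
    if extra:
        arrays["extra_yaml"] = np.array(yaml.safe_dump(extra, sort_keys=True))
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path) -> tuple[SegmentationModel, dict]:
    with np.load(path, allow_pickle=False) as data:
        cfg = ModelConfig.from_yaml(str(data["config_yaml"]))
        model = SegmentationModel(cfg)
        state = {k[len("param/"):]: data[k] for k in data.files
                 if k.startswith("param/")}
        model.load_state_dict(state)
        extra = (yaml.safe_load(str(data["extra_yaml"]))
                 if "extra_yaml" in data.files else {})
    return model, extra
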