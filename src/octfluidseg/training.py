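"""Training, evaluation and prediction drivers.

Optimization follows the reference recipe: AdamW (weight decay 0.01), base
learning rate 1e-4 with a polynomial ("poly") decay lr0 * (1 - t/T)^power,
batches of 8 images resized to the model's input size, and random
flip/rotation augmentation.  The compound cross-entropy + Dice loss comes
from :mod:`octfluidseg.losses_metrics`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.ndimage as ndi
import yaml

from . import autodiff as ad
from .autodiff import AdamW, Tensor
from .losses_metrics import LossConfig, compound_loss, segmentation_metrics
from .network import ModelConfig, SegmentationModel, save_checkpoint
from .synthetic_data import SegmentationSample, to_model_input

__all__ = ["TrainConfig", "poly_lr", "clip_gradients", "augment_sample", "foreground_dice",
           "train_model", "predict_masks", "overlay_mask", "evaluate_model"]

logger = logging.getLogger("octfluidseg")


@dataclass
class TrainConfig:
    """Optimization hyperparameters (defaults follow the reference recipe)."""

    optimizer: str = "adamw"
    weight_decay: float = 0.01
    beta1: float = 0.9
    beta2: float = 0.999
    lr: float = 1e-4
    schedule: str = "poly"
    power: float = 0.9
    epochs: int = 150
    batch_size: int = 8
    augment_flip: bool = True
    augment_rotation: float = 15.0   # degrees, uniform in +/- this range
    input_size: int = 512
    lambda_ce: float = 0.5
    lambda_dice: float = 0.5
    seed: int = 0
    max_steps: int | None = None     # optional hard cap on optimizer steps
    stop_at_dice: float | None = None  # early stop once train Dice reaches this
    warmup_steps: int = 0            # linear ramp 0 -> lr before poly decay
    clip_grad_norm: float | None = None  # global gradient-norm clipping

    def validate(self) -> None:
        if self.optimizer != "adamw":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        if self.schedule != "poly":
            raise ValueError(f"unsupported schedule {self.schedule!r}")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        LossConfig(self.lambda_ce, self.lambda_dice).validate()

    def loss_config(self) -> LossConfig:
        return LossConfig(self.lambda_ce, self.lambda_dice)

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "TrainConfig":
        d = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(d) - known
        if extra:
            raise ValueError(f"unknown train config keys: {sorted(extra)}")
        return cls(**d)


def poly_lr(lr0: float, step: int, total: int, power: float = 0.9,
            warmup: int = 0) -> float:
    """Polynomial decay lr0 * (1 - t/T)^power; nonincreasing, 0 at t = T.

    An optional linear warmup ramps from 0 to lr0 over the first ``warmup``
    steps; the poly decay then runs over the remaining budget.
    """
    if warmup > 0 and step < warmup:
        return lr0 * (step + 1) / warmup
    frac = min(max((step - warmup) / max(total - warmup, 1), 0.0), 1.0)
    return lr0 * (1.0 - frac) ** power


def clip_gradients(params, max_norm: float) -> float:
    """Scale gradients so their global L2 norm is at most ``max_norm``."""
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad ** 2).sum())
    norm = total ** 0.5
    if norm > max_norm:
        scale = max_norm / (norm + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad = p.grad * scale
    return norm


def augment_sample(image: np.ndarray, mask: np.ndarray,
                   rng: np.random.Generator, flip: bool = True,
                   rotation: float = 15.0) -> tuple[np.ndarray, np.ndarray]:
    """Random horizontal/vertical flip and rotation.

    Images rotate with bilinear interpolation, masks with nearest-neighbor
    so no new labels appear.
    """
    if flip and rng.random() < 0.5:
        image, mask = image[:, ::-1], mask[:, ::-1]
    if flip and rng.random() < 0.5:
        image, mask = image[::-1, :], mask[::-1, :]
    if rotation > 0:
        angle = rng.uniform(-rotation, rotation)
        image = ndi.rotate(image, angle, reshape=False, order=1, mode="nearest")
        mask = ndi.rotate(mask, angle, reshape=False, order=0, mode="nearest")
    return np.ascontiguousarray(image), np.ascontiguousarray(mask)


def foreground_dice(pred: np.ndarray, true: np.ndarray,
                    num_classes: int = 4) -> float:
    """Mean Dice over foreground classes, pixels pooled across the batch."""
    rep = segmentation_metrics(pred, true, num_classes)
    vals = [v["DSC"] for c, v in rep["per_class"].items() if c != "background"]
    vals = [v for v in vals if np.isfinite(v)]
    return float(np.mean(vals)) if vals else float("nan")


def _provenance(model_cfg: ModelConfig, train_cfg: TrainConfig) -> dict:
    import scipy
    blob = (model_cfg.to_yaml() + train_cfg.to_yaml()).encode()
    return {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": train_cfg.seed,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pyyaml": yaml.__version__,
    }


def train_model(model: SegmentationModel, samples: list[SegmentationSample],
                train_cfg: TrainConfig,
                checkpoint_path: str | Path | None = None) -> dict:
    """Fit the model on in-memory samples; returns the training history.

    Logs per-epoch loss and pooled foreground Dice of the training
    predictions; keeps the best-Dice checkpoint if a path is given.  A
    ``stop_at_dice`` threshold ends training early once reached.
    """
    train_cfg.validate()
    if not samples:
        raise ValueError("empty training set")
    S = model.cfg.input_size
    for s in samples:
        if s.image.shape != (S, S):
            raise ValueError(
                f"sample shape {s.image.shape} does not match model input "
                f"size {S}; load with image_size={S}")
    rng = np.random.default_rng(train_cfg.seed)
    opt = AdamW(list(model.parameters()), lr=train_cfg.lr,
                betas=(train_cfg.beta1, train_cfg.beta2),
                weight_decay=train_cfg.weight_decay)
    loss_cfg = train_cfg.loss_config()
    n = len(samples)
    steps_per_epoch = max(1, n // train_cfg.batch_size)
    total_steps = train_cfg.epochs * steps_per_epoch
    if train_cfg.max_steps is not None:
        total_steps = min(total_steps, train_cfg.max_steps)

    prov = _provenance(model.cfg, train_cfg)
    logger.info("training start: %s", prov)
    history = {"provenance": prov, "epochs": [], "steps": 0,
               "best_dice": float("-inf")}
    step = 0
    t0 = time.time()
    stop = False
    for epoch in range(train_cfg.epochs):
        if stop or step >= total_steps:
            break
        order = rng.permutation(n)
        losses, dices = [], []
        for b in range(steps_per_epoch):
            if step >= total_steps:
                break
            idx = order[b * train_cfg.batch_size:(b + 1) * train_cfg.batch_size]
            if idx.size == 0:
                break
            imgs, masks = [], []
            for i in idx:
                img, msk = augment_sample(
                    samples[i].image, samples[i].mask, rng,
                    flip=train_cfg.augment_flip,
                    rotation=train_cfg.augment_rotation)
                imgs.append(img)
                masks.append(msk)
            x = Tensor(to_model_input(imgs))
            y = np.stack(masks)
            logits = model(x)
            loss = compound_loss(logits, y, loss_cfg)
            model.zero_grad()
            loss.backward()
            if train_cfg.clip_grad_norm is not None:
                clip_gradients(opt.params, train_cfg.clip_grad_norm)
            opt.lr = poly_lr(train_cfg.lr, step, total_steps, train_cfg.power,
                             train_cfg.warmup_steps)
            opt.step()
            step += 1
            losses.append(float(loss.data))
            dice = foreground_dice(logits.data.argmax(axis=1), y)
            dices.append(dice)
            if (train_cfg.stop_at_dice is not None
                    and np.isfinite(dice) and dice >= train_cfg.stop_at_dice):
                stop = True
                break
        epoch_loss = float(np.mean(losses)) if losses else float("nan")
        epoch_dice = float(np.nanmean(dices)) if dices else float("nan")
        history["epochs"].append({"epoch": epoch, "loss": epoch_loss,
                                  "dice": epoch_dice,
                                  "lr": opt.lr, "steps": step})
        logger.info("epoch %d: loss=%.4f dice=%.4f lr=%.2e (%.1fs)",
                    epoch, epoch_loss, epoch_dice, opt.lr, time.time() - t0)
        if checkpoint_path is not None and epoch_dice > history["best_dice"]:
            save_checkpoint(model, checkpoint_path,
                            extra={"epoch": epoch, "dice": epoch_dice,
                                   **prov})
        history["best_dice"] = max(history["best_dice"], epoch_dice)
    history["steps"] = step
    return history


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def predict_masks(model: SegmentationModel,
                  samples: list[SegmentationSample],
                  batch_size: int = 8) -> np.ndarray:
    """Argmax masks (N, S, S) for a list of samples, batched, no gradients."""
    out = []
    for i in range(0, len(samples), batch_size):
        x = Tensor(to_model_input(samples[i:i + batch_size]))
        out.append(model.predict(x))
    return np.concatenate(out, axis=0)


# fixed display convention: red = IRF, blue = SRF, green = PED
OVERLAY_COLORS = {1: (255, 0, 0), 2: (0, 0, 255), 3: (0, 255, 0)}


def overlay_mask(image: np.ndarray, mask: np.ndarray,
                 alpha: float = 0.5) -> np.ndarray:
    """Blend class colors onto a grayscale image; background pixels untouched."""
    rgb = np.repeat((np.clip(image, 0, 1) * 255).astype(np.float64)[..., None],
                    3, axis=-1)
    for label, color in OVERLAY_COLORS.items():
        sel = mask == label
        rgb[sel] = (1 - alpha) * rgb[sel] + alpha * np.asarray(color, float)
    return rgb.round().astype(np.uint8)


def evaluate_model(model: SegmentationModel,
                   samples: list[SegmentationSample],
                   batch_size: int = 8) -> list[dict]:
    """Per-sample metric reports for a dataset."""
    preds = predict_masks(model, samples, batch_size)
    return [segmentation_metrics(p[None], s.mask[None].astype(int),
                                 model.cfg.num_classes)
            for p, s in zip(preds, samples)]
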