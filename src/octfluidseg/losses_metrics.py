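"""Compound segmentation loss and the evaluation metric suite.

Training loss: L = lambda1 * L_ce + lambda2 * L_dice (both weights default
0.5).  L_ce is the pixel-mean multi-class cross-entropy; L_dice is one minus
the soft Dice overlap 2*sum(y*p) / (sum(y) + sum(p)), averaged over the
foreground classes (IRF/SRF/PED) with an epsilon smoothing term so empty
classes are well-defined.

Evaluation metrics per class, from hard masks X (prediction) and Y (truth):
DSC = 2|X∩Y| / (|X|+|Y|), IoU = |X∩Y| / |X∪Y|, RVD = ||X|-|Y|| / |Y|, and
BACC = (sensitivity + specificity) / 2 from the one-vs-rest confusion
counts.  A class absent from both masks yields undefined (NaN) metrics and
is excluded from macro averages rather than scored 0 or 1.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "LossConfig",
    "cross_entropy_loss",
    "dice_loss",
    "compound_loss",
    "ConfusionMatrix",
    "confusion_matrix",
    "segmentation_metrics",
    "aggregate_metrics",
    "write_metrics_report",
]

CLASS_NAMES = ("background", "IRF", "SRF", "PED")
DICE_EPS = 1e-6


@dataclass
class LossConfig:
    """Weights of the cross-entropy and Dice terms."""

    lambda_ce: float = 0.5
    lambda_dice: float = 0.5
    include_background_dice: bool = False

    def validate(self) -> None:
        if self.lambda_ce < 0 or self.lambda_dice < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.lambda_ce + self.lambda_dice <= 0:
            raise ValueError("at least one loss weight must be positive")


def _one_hot(y: np.ndarray, num_classes: int) -> np.ndarray:
    if y.min() < 0 or y.max() >= num_classes:
        raise ValueError(
            f"labels must lie in [0, {num_classes}), got range "
            f"[{y.min()}, {y.max()}]")
    return np.transpose(np.eye(num_classes)[y.astype(int)], (0, 3, 1, 2))


def cross_entropy_loss(pred: Tensor, y: np.ndarray,
                       from_logits: bool = True) -> Tensor:
    """Pixel-mean cross-entropy  -mean_i log p_i[y_i].

    ``pred`` is (B, K, H, W) — raw logits by default, or probabilities with
    ``from_logits=False``.
    """
    K = pred.shape[1]
    onehot = _one_hot(np.asarray(y), K)
    logp = ad.log_softmax(pred, axis=1) if from_logits else ad.log(pred)
    return -ad.reduce_mean(ad.reduce_sum(ad.mul(logp, onehot), axis=1))


def dice_loss(pred: Tensor, y: np.ndarray, from_logits: bool = True,
              include_background: bool = False) -> Tensor:
    """Soft Dice loss, averaged over (by default) the foreground classes.

    Sums run over every pixel of the batch; the epsilon term keeps classes
    that are empty in both prediction and truth at zero loss.
    """
    K = pred.shape[1]
    onehot = _one_hot(np.asarray(y), K)
    p = ad.softmax(pred, axis=1) if from_logits else pred
    first = 0 if include_background else 1
    terms = []
    for c in range(first, K):
        pc, yc = p[:, c], Tensor(onehot[:, c])
        inter = ad.reduce_sum(ad.mul(pc, yc))
        sums = ad.reduce_sum(pc) + ad.reduce_sum(yc)
        dice = ad.mul(2.0 * inter + DICE_EPS, ad.power(sums + DICE_EPS, -1.0))
        terms.append(1.0 - dice)
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return ad.mul(total, 1.0 / len(terms))


def compound_loss(pred: Tensor, y: np.ndarray,
                  cfg: LossConfig | None = None,
                  from_logits: bool = True) -> Tensor:
    """Weighted sum lambda_ce * CE + lambda_dice * Dice."""
    cfg = cfg or LossConfig()
    cfg.validate()
    ce = cross_entropy_loss(pred, y, from_logits)
    dc = dice_loss(pred, y, from_logits, cfg.include_background_dice)
    return ad.add(ad.mul(ce, cfg.lambda_ce), ad.mul(dc, cfg.lambda_dice))


# ---------------------------------------------------------------------------
# hard-mask metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """Per-class one-vs-rest counts plus the full K x K matrix.

    ``matrix[i, j]`` counts pixels with true class i predicted as class j.
    """

    matrix: np.ndarray
    class_names: tuple[str, ...] = field(default=CLASS_NAMES)

    @property
    def num_classes(self) -> int:
        return self.matrix.shape[0]

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    def counts(self, c: int) -> dict[str, int]:
        m = self.matrix
        tp = int(m[c, c])
        fn = int(m[c].sum() - tp)
        fp = int(m[:, c].sum() - tp)
        tn = self.total - tp - fn - fp
        return {"TP": tp, "FN": fn, "FP": fp, "TN": tn}

    def normalized(self) -> np.ndarray:
        """Row-normalized matrix (recall per true class); NaN for empty rows."""
        rows = self.matrix.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(rows > 0, self.matrix / rows, np.nan)

    def to_png(self, path, normalized: bool = True) -> None:
        """Render the matrix as a heatmap image (requires matplotlib)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        mat = self.normalized() if normalized else self.matrix.astype(float)
        names = self.class_names[:self.num_classes]
        fig, ax = plt.subplots(figsize=(4.5, 4))
        im = ax.imshow(np.nan_to_num(mat), cmap="Blues", vmin=0,
                       vmax=1 if normalized else None)
        ax.set_xticks(range(len(names)), names, rotation=45, ha="right")
        ax.set_yticks(range(len(names)), names)
        ax.set_xlabel("predicted")
        ax.set_ylabel("true")
        for i in range(len(names)):
            for j in range(len(names)):
                v = mat[i, j]
                ax.text(j, i, "-" if not np.isfinite(v) else
                        (f"{v:.2f}" if normalized else f"{int(v)}"),
                        ha="center", va="center", fontsize=8)
        fig.colorbar(im, ax=ax, fraction=0.046)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)

    def to_csv(self, path, normalized: bool = True) -> None:
        mat = self.normalized() if normalized else self.matrix
        names = self.class_names[:self.num_classes]
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["true\\pred", *names])
            for name, row in zip(names, mat):
                w.writerow([name] + [f"{v:.4f}" if normalized else int(v)
                                     for v in row])


def confusion_matrix(pred: np.ndarray, true: np.ndarray,
                     num_classes: int = 4) -> ConfusionMatrix:
    pred = np.asarray(pred).ravel().astype(int)
    true = np.asarray(true).ravel().astype(int)
    if pred.shape != true.shape:
        raise ValueError("prediction and truth differ in size")
    for name, arr in (("prediction", pred), ("truth", true)):
        if arr.min() < 0 or arr.max() >= num_classes:
            raise ValueError(f"{name} labels outside [0, {num_classes})")
    m = np.bincount(true * num_classes + pred,
                    minlength=num_classes * num_classes)
    return ConfusionMatrix(m.reshape(num_classes, num_classes))


def segmentation_metrics(pred: np.ndarray, true: np.ndarray,
                         num_classes: int = 4) -> dict:
    """Per-class DSC / IoU / RVD / BACC plus the confusion matrix.

    X is the predicted region, Y the ground truth of each class.  Undefined
    cases are NaN: every metric when the class is absent from both masks;
    RVD when the truth is empty but the prediction is not.
    """
    pred, true = np.asarray(pred), np.asarray(true)
    if pred.shape != true.shape:
        raise ValueError(
            f"mask shapes differ: {pred.shape} vs {true.shape}")
    cm = confusion_matrix(pred, true, num_classes)
    per_class: dict[str, dict[str, float]] = {}
    for c in range(num_classes):
        cnt = cm.counts(c)
        tp, fn, fp, tn = cnt["TP"], cnt["FN"], cnt["FP"], cnt["TN"]
        x, y = tp + fp, tp + fn  # |X|, |Y|
        if x == 0 and y == 0:
            vals = dict.fromkeys(("DSC", "IoU", "RVD", "BACC"), float("nan"))
        else:
            dsc = 2.0 * tp / (x + y)
            iou = tp / (x + y - tp)
            rvd = abs(x - y) / y if y > 0 else float("nan")
            sens = tp / y if y > 0 else float("nan")
            spec = tn / (tn + fp) if tn + fp > 0 else float("nan")
            bacc = 0.5 * (sens + spec)
            vals = {"DSC": dsc, "IoU": iou, "RVD": rvd, "BACC": bacc}
        per_class[CLASS_NAMES[c] if c < len(CLASS_NAMES) else f"class{c}"] = vals
    return {"per_class": per_class, "confusion": cm}


def aggregate_metrics(reports: list[dict]) -> dict:
    """Macro-average metric reports over samples, skipping undefined entries.

    Foreground means pool the three fluid classes; a pooled confusion matrix
    is summed over samples.
    """
    if not reports:
        raise ValueError("no reports to aggregate")
    classes = list(reports[0]["per_class"])
    agg: dict[str, dict[str, float]] = {}
    for cls in classes:
        agg[cls] = {}
        for metric in ("DSC", "IoU", "RVD", "BACC"):
            vals = [r["per_class"][cls][metric] for r in reports]
            vals = [v for v in vals if np.isfinite(v)]
            agg[cls][metric] = float(np.mean(vals)) if vals else float("nan")
    fg = [c for c in classes if c != "background"]
    fg_mean = {}
    for metric in ("DSC", "IoU", "RVD", "BACC"):
        vals = [agg[c][metric] for c in fg if np.isfinite(agg[c][metric])]
        fg_mean[metric] = float(np.mean(vals)) if vals else float("nan")
    pooled = sum((r["confusion"].matrix for r in reports[1:]),
                 reports[0]["confusion"].matrix.copy())
    return {"per_class": agg, "foreground_mean": fg_mean,
            "confusion": ConfusionMatrix(pooled)}


def write_metrics_report(agg: dict, csv_path=None, json_path=None) -> None:
    """Serialize an aggregated report; RVD also gets a x100 convenience column."""
    rows = []
    for cls, vals in agg["per_class"].items():
        rows.append({"class": cls, **{k: vals[k] for k in
                                      ("DSC", "IoU", "RVD", "BACC")},
                     "RVDx100": vals["RVD"] * 100})
    rows.append({"class": "foreground_mean",
                 **{k: agg["foreground_mean"][k] for k in
                    ("DSC", "IoU", "RVD", "BACC")},
                 "RVDx100": agg["foreground_mean"]["RVD"] * 100})
    if csv_path is not None:
        with open(csv_path, "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=list(rows[0]))
            w.writeheader()
            w.writerows(rows)
    if json_path is not None:
        payload = {"per_class": agg["per_class"],
                   "foreground_mean": agg["foreground_mean"],
                   "confusion_matrix": agg["confusion"].matrix.tolist()}
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=2, allow_nan=True)
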