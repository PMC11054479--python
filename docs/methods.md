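# Methods

## Problem and model

The package segments three retinal fluid compartments in 2-D OCT B-scans —
intraretinal fluid (IRF), subretinal fluid (SRF) and pigment epithelial
detachment (PED) — as a 4-class per-pixel labelling problem (background plus
the three fluid classes).

The model is a U-shaped encoder/decoder that mixes convolutional and
attention blocks:

* **Stem.** A 4×4 convolution with stride 4 patchifies the input to
  H/4 × W/4 with C₀ channels, followed by LayerNorm. The stage-i feature map
  is H/2^(i+2) × W/2^(i+2) with 2^i·C₀ channels; with the default C₀ = 96
  and 512×512 inputs the four stages run at 128/64/32/16 resolution with
  96/192/384/768 channels.
* **Encoder stages.** Each stage applies three ConvNeXt-V2 blocks
  (depthwise 7×7 → LayerNorm → pointwise expansion ×4 → GELU → global
  response normalization → pointwise reduction, with a residual skip), then
  two windowed-attention Transformer blocks (8×8 windows, heads 3/6/12/24
  by stage, alternating regular and shifted windows), then the region-aware
  spatial attention (RASA) module. A LayerNorm + 2×2 stride-2 convolution
  between stages halves resolution and doubles channels.
* **Bottleneck.** Three ConvNeXt-V2 blocks at the deepest resolution.
* **Decoder.** Four stages of two Transformer blocks each (mirroring the
  encoder stage at the same resolution), fed by fused skip connections;
  between stages a bilinear ×2 upsample + 3×3 convolution doubles
  resolution and halves channels. The last decoder feature (at H/4) is
  upsampled ×4 bilinearly and a 1×1 convolution produces the class logits.

### Windowed attention

Tokens of each L×L window are projected to Q/K/V with C×C matrices, split
into k heads of dimension C/k, attended with softmax(QKᵀ/√d_k)V, then
concatenated and output-projected; a learnable positional table of shape
(L², C), zero-initialized, is added to each window's output tokens *after*
the output projection (deliberately different from the relative-position
bias placed inside the softmax in other window-attention designs).
Alternate blocks cyclically shift the map by ⌊L/2⌋ before partitioning and
shift back afterwards; token pairs whose pre-shift positions were not
spatially contiguous are masked with −10⁹ logits. Windows larger than the
map (reached only in heavily scaled-down configurations) are clamped to the
map size and the shift is disabled — a single window already covers
everything.

### Global response normalization

For channels-last features, G(x)_c is the spatial L2 norm of channel c,
N(x)_c = G(x)_c / (mean_c G(x) + 1e-6), and the output is
gain·(x·N(x)) + bias + x with per-channel gain/bias initialized to zero, so
a fresh block starts as the identity. A 1e-12 constant inside the square
root keeps the gradient finite on exactly-zero channels.

### Region-aware spatial attention (RASA)

Fluid lesions concentrate in the central rows of a B-scan. RASA splits the
feature map into four equal horizontal bands (top-down), computes for each
band a spatial attention map — channel mean and max pooled to 2 channels,
four parallel same-padded convolutions (1×1/3×3/5×5/7×7, each 2→1 channel),
concatenation, a 7×7 convolution 4→1, sigmoid — re-assembles the bands
along height, normalizes with a softmax, and multiplies the input by the
resulting map (broadcast over channels). One shared attention head serves
all four bands; the bands compete through the softmax, not through separate
weights. Design choices made here:

* **Softmax axis.** The normalization axis is the full height axis,
  independently per column (each column of the map sums to 1), which makes
  the four regions compete at every lateral position. A `hw-flat` option
  normalizes over the whole plane instead.
* **Sigmoid before softmax** is kept literally even though the softmax
  re-normalizes: the sigmoid bounds the band logits to (0, 1), which keeps
  the softmax temperature-stable.
* No rescaling is applied after the softmax, so the module scales features
  down by roughly 1/H on average; the following stages compensate.
* Maps shorter than four rows (only in extreme scaled-down configs) are
  treated as a single band.

### Multi-scale skip fusion (SMFFA)

Each encoder stage contributes two features: its output F_i and a tap
F_i_next taken right after the stage's ConvNeXt blocks, before the
Transformer blocks. The preceding stage's feature (2× resolution, C/2
channels) is downsampled with a 2×2 stride-2 convolution that preserves its
channel count; the succeeding stage's feature (½ resolution, 2C channels)
is upsampled bilinearly. Every feature then passes a dual-kernel projection
(parallel 3×3 and 5×5 convolutions, each emitting C/2 channels of the
*current* stage, concatenated to C) — this is where all channel counts are
harmonized. The current-stage pair is added; the sum is added to each
resampled neighbor; each fused map passes a dual-pool channel attention
(GAP and GMP summaries through a shared bias-free bottleneck W₂·ReLU(W₁·s),
summed, sigmoid), with an independent parameter set per branch; the
attended branches are concatenated and reduced to C channels by a 3×3
convolution. Boundary stages have one neighbor; their single branch feeds
the final convolution alone (which then maps C→C instead of 2C→C).

The channel-attention reduction ratio defaults to 16 (the
squeeze-excitation convention, giving a 6-unit bottleneck at the narrowest
default stage). Scaled-down configurations should scale it down as well
(the 64×64 test configuration uses 4) so the bottleneck keeps several
hidden units; with a single unit the ReLU can die at initialization.

### Skip wiring in the decoder

The fused skip is concatenated with the decoder feature along channels and
projected back to the stage width by a 1×1 convolution before the
Transformer blocks — standard U-shape practice. With fusion disabled
(ablation), the raw encoder stage output takes the skip's place.

## Loss

L = λ₁·L_ce + λ₂·L_dice with λ₁ = λ₂ = 0.5. L_ce is pixel-mean multi-class
cross-entropy. L_dice = 1 − mean_c 2Σy_c p_c / (Σy_c + Σp_c) over the three
foreground classes (background excluded by default; a switch includes it),
with sums over all pixels of the batch and ε = 1e-6 smoothing in numerator
and denominator so classes empty in both prediction and truth contribute
zero loss.

## Metrics

Per class, from hard masks X (prediction) and Y (truth):
DSC = 2|X∩Y|/(|X|+|Y|), IoU = |X∩Y|/|X∪Y| (the identity
IoU = DSC/(2−DSC) holds and is fuzz-tested), RVD = ||X|−|Y||/|Y|, and
BACC = (TP/(TP+FN) + TN/(TN+FP))/2 computed one-vs-rest per class. A class
absent from both masks is *undefined* (NaN) and excluded from macro
averages — never scored 0 or 1; RVD is also undefined when the truth is
empty. Reports are written per B-scan and macro-averaged; the pooled
confusion matrix (and the pixel-pooled Dice used to monitor training)
treats the whole set as one volume. RVD is reported both raw and ×100.

## Training recipe

AdamW (weight decay 0.01), base learning rate 1e-4 with polynomial decay
lr₀·(1 − t/T)^0.9, batches of 8 images at 512×512, random horizontal and
vertical flips plus rotation uniform in ±15° (bilinear for images,
nearest-neighbor for masks so no labels are invented), 150 epochs. The
rotation range and poly power are configurable; optional extras — linear
warmup, global gradient-norm clipping, Adam β₂ — are exposed for small-data
regimes where the defaults are unstable. No pre- or post-processing stages
exist anywhere in the pipeline.

## Synthetic phantoms

The generator renders a retinal slab of `layer_count` alternating-intensity
bands between two smooth curved surfaces placed in the central half of the
image, multiplies by clipped Gaussian speckle (σ = 0.18), and inserts
irregular lesions (ellipses with smooth angular radius modulation):
IRF as dark blobs inside the slab, SRF as dark pockets under the deepest
band, PED as dome bumps rising from the lowest surface. These
class-conditional placement rules are the generator's own convention,
chosen so the classes have distinguishable spatial statistics.
`central_concentration` ∈ [0,1] shrinks the admissible row range of IRF
centers around the image middle; at 1.0 every lesion center lies in the
central quarter of rows. Everything is deterministic in the seed; sample i
of a dataset uses seed + i.

What the phantoms do **not** emulate: physically correct OCT speckle
statistics (multiplicative Gaussian, not Rayleigh/gamma), vendor-specific
appearance, vessel shadows, motion artifacts, or anatomically realistic
layer topology. Passing tests on phantoms therefore demonstrates that the
architecture, losses, metrics and training loop are correctly implemented
and can fit structured data — not that the model reaches any particular
accuracy on clinical OCT.

## Scaled-down experiment

The overfitting check trains the reduced configuration (C₀ = 16, 64×64
inputs, window 4, heads 1/2/4/8, channel-attention reduction 4) on eight
phantoms (lesion semi-axes 3–10 px so lesions stay resolvable at 1/8 the
reference scale) with lr 5e-3, β₂ 0.95, 30 warmup steps, gradient-norm
clip 1.0, no augmentation, full-batch updates, at most 300 steps. It must
reach pooled foreground Dice ≥ 0.90 on its own training set for at least
2 of 3 seeds. These problem sizes keep the whole experiment at a few
minutes on a single CPU core.

## Numerical infrastructure

The network runs on a small reverse-mode automatic-differentiation engine
written on NumPy (float64 throughout): broadcast arithmetic, batched
matmul, grouped/strided/padded 2-D convolution via strided im2col views,
LayerNorm, softmax/log-softmax, exact-erf GELU, bilinear resampling as a
separable linear operator with edge clamping (align-corners-false
convention), reductions, slicing, padding and cyclic roll — each op with an
analytic backward pass verified against central finite differences.
Weight initialization is truncated normal (σ = 0.02, clipped at ±2σ) for
projections, zeros for biases, GRN gains/biases and positional tables, all
drawn from a seeded generator embedded in the model config, so identical
configs build bit-identical models.

## Known limitations

* 2-D B-scans only; volumes are ordered slice sets, and no 3-D context is
  used.
* Pretrained encoder weights are supported only as an external state-dict
  hook; no pretraining is bundled.
* The engine is single-threaded NumPy: full-scale (512×512, C₀ = 96)
  training is functional but intended for correctness checks, not
  large-scale experiments.
* Single-token attention windows and single-row softmaxes (deepest stage of
  extremely small configurations) are constant functions; their query/key
  parameters receive no gradient there by construction.
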