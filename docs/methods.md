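# Methods

## Model

The segmentation network adapts a frozen, self-supervised ViT-large retinal
encoder to joint optic-disc/optic-cup segmentation. The forward path is

```
input (B,3,H,W)
  → Pre-adapter            → canvas (B,3,224,224)
  → patch embed + pos emb  → tokens (B,196,1024), no class token
  → 24 ViT blocks          → taps after blocks 6,12,18,24
  → mask-transformer (2 blocks, K class embeddings)
                           → mask maps (B,K,14,14)
  → Post-adapter ×2-upsampling tower with CBAM skip fusion
                           → logits (B,K,H,W) → softmax → argmax
```

Assumptions inherited from the design: inputs are disc-centred crops (the
preprocessing module provides them); the cup lies inside the disc, so label
masks use 0 = background, 1 = disc rim, 2 = cup and the evaluated OD region
is the union {1,2}; the encoder representation is strong enough that only
bottleneck adapters (1024→128→1024, GELU, residual) need training inside the
backbone.

Choices the published description leaves open, decided here once:

- **Decoder internals** follow the standard mask-transformer design: input
  projection 1024→1024, pre-norm blocks with MLP ratio 4 and qkv biases,
  learned square projection matrices (no bias, init `N(0, d⁻¹)`) for patch
  and class features, L2 normalisation before the inner product, and a
  LayerNorm over the K mask scores. With these conventions the canonical
  K=3 model has 35,563,499 tunable parameters (35.56 M; the original
  implementation reports 35.57 M, a 0.02 % difference attributable to
  bias/normalisation bookkeeping) and the Pre-adapter has 40,710 (~40 k).
- **First Post-adapter block input width** equals K (2 or 3): the mask maps
  have K channels, and the published "three input channels" is read as the
  joint-task instance.
- **Class tokens**: the fine-tuned encoder runs with none (196 tokens, 196
  positional embeddings); a leading class-token row in imported checkpoints
  is dropped.
- **Truncated normal init** for decoder class embeddings and positional
  embeddings: std 0.02, truncation ±2σ.
- **CBAM**: channel-attention reduction 16 (floor 4 for narrow configs),
  shared two-layer gate MLP with biases, 7×7 spatial gate, sigmoid gates.
- **Bicubic convention** everywhere: Catmull-Rom kernel (a = −0.5),
  half-pixel-centred sampling, clamped edges, expressed as separable linear
  operators so the same matrices serve forward, backward and the NumPy-side
  restoration path. "Inter-area" resizing is exact pixel-area-overlap
  averaging, likewise separable.
- **Normalization**: batch norm in CNN blocks by default; group norm
  (8 groups) is the documented option for small batches and is the tiny
  configuration's default. Both have identical parameter counts.
- **Adapters sit in every encoder block**, between the first LayerNorm and
  the attention; `unfreeze_last_n` exposes partial freezing as a config
  flag.
- **OD-only models** honestly use K=2 (two class embeddings); K is a config
  field, so the 3-token variant remains available.

## Numerical backend

The network, reverse-mode autodiff, and AdamW are implemented on NumPy with
numba kernels for stride-1 convolution (shift-multiply-accumulate; ~20
GFLOP/s on one core) and fused batch/group-norm primitives with analytic
backward. Every operator's gradient is validated against central finite
differences in the test suite. Float32 is the working precision; the
finite-difference tests run in float64. Softmax and layer norm are computed
in numerically stable shifted form; cross-entropy clips probabilities at
1e-12; soft Dice uses smoothing 1e-5 in numerator and denominator, averaged
over classes including background (a flag excludes it). Argmax ties resolve
to the lowest class index. Nearest-rank percentiles (⌈q·n⌉-th order
statistic) make HD95 reproducible by enumeration; empty-versus-nonempty
region comparisons return the image diagonal and set a flag rather than
infinity, so aggregation stays finite; two empty regions score DSC 1 and
distance 0.

## Training and evaluation defaults

| parameter | default | note |
|---|---|---|
| learning rate | 0.001 | AdamW, constant (no schedule, no clipping) |
| weight decay | 0.001 | decoupled |
| batch size | 32 (8 in CPU-scale runs) | group norm below batch 8 |
| seed | 112316 | drives init, shuffling, augmentation |
| max epochs | 20,000 available; 500 default here | selection by best validation DSC, checked every epoch |
| Dice smoothing | 1e-5 | numerator and denominator |
| bootstrap | 10,000 resamples, percentile 95 % CI | seeded |
| crop | 800² window, 256² input | per-dataset `crop_size` in the manifest |
| OD detector filters | area ∈ [0.05 %, 15 %] of image, circularity 4πA/P² ≥ 0.5 | config-exposed; thresholds chosen to pass plausible discs and reject specks and smears |
| rotation range | ±30°, p=0.5 | "random rotation" is otherwise unparameterised |
| photometric ranges | blur σ∈[0.5,1.5] p=0.2; noise σ≤0.05 p=0.15; brightness ±0.1, contrast [0.75,1.25], gamma [0.7,1.5], each p=0.15 | deep-stacked-transformations style |

Augmentation strategies: `none`, `spatial` (rotation + flips), `designed`
(spatial + the five photometric transforms); geometric transforms are applied
identically to image (bicubic) and mask (nearest).

## Problem sizes

The canonical geometry (224 canvas, ViT-large) is instantiated for
construction-time checks (parameter accounting, shape contracts). Training
and end-to-end tests run a tiny configuration chosen as this package's
CPU-scale working point: canvas 64 (grid 4 — the same `grid·2⁴ = canvas`
law as the canonical model), depth 4, width 64, 4 heads, adapter width 16,
decoder width 64, skip width 16, input 64, group norm. Overfitting eight
64-pixel phantoms to validation DSC ≥ 0.95 takes ≈ 60–80 epochs (about one
to two minutes on one core); all geometry, freezing, residual-identity and
loss properties are exercised at this scale and are size-independent by
construction.

## What the phantoms do and do not establish

`synthetic.generate_phantom` renders the structural essentials of a
disc-centred fundus photograph — circular field of view with radial
illumination fall-off, dark curved vessel strokes, bright elliptical disc
with a brighter interior cup (CDR = √(cup area/disc area), drawn from
U(0.3, 0.7) by default, disc radius 40–70 px at 512²), Gaussian sensor
noise — with pixel-exact masks, and four appearance-domain presets that
shift colour cast, contrast, brightness, noise and disc-size distribution.
Passing tests on phantoms establishes that the implementation is correct
and trainable: gradients flow where intended, geometry round-trips, metrics
match oracles, domain presets produce measurable appearance shifts. They do
not establish clinical performance: phantoms lack pathology, vessel trees,
camera optics, annotation ambiguity and the texture statistics of real
fundus images, so DSC values obtained on them say nothing about accuracy on
clinical data. Reproducing the dataset-level results of the original study
requires its five clinical datasets and GPU-scale training, both outside
this package's scope.

## Known limitations

- Stride-1 convolutions only (the architecture needs nothing else); no
  mixed precision, no distributed training, no LR schedules.
- Checkpoint interchange is `.npz` with MAE/ViT-large naming; converting a
  torch `.pth` requires a one-line external export
  (`np.savez(path, **{k: v.numpy() for k, v in state_dict.items()})`).
- The coarse OD detector interface accepts any binary mask (ground truth, an
  external model, a thresholded heuristic); the package does not ship a
  learned detector.
- Batch-norm running statistics make train/eval behaviour differ at tiny
  batch sizes; the group-norm option avoids this and is the tiny config
  default.
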