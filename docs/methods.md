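# Methods

## The attention block

StarMA re-weights a rank-4 feature map (B, C, H, W) without changing its
shape. Channels are partitioned into `G` contiguous groups (default `G = 8`)
that are folded into the batch axis and processed by shared-weight branches
— so the block's parameter count depends on the per-group width `C' = C/G`,
not on `C`.

**Axial descriptors.** The per-height descriptor `x_h` (C'×H×1) is the mean
over the width axis and the per-width descriptor `x_w` (C'×1×W) the mean over
height. The two orientations are deliberately asymmetric in the equations'
kernel naming; this implementation follows the coordinate-attention lineage
(descriptor length H for the height branch) so that the concatenated strip
has length `H + W`.

**Star-shape structure.** The strip is downsampled along its length by a 1×1
convolution with stride 2 (output length `ceil((H+W)/2)`), passed through two
independent width-preserving 1×1 convolutions — one followed by exact-erf
GELU — multiplied elementwise (the star operation), squashed by a sigmoid,
and restored to length `H + W` by nearest-neighbour interpolation (a `linear`
option exists). The strip is split at `H` into broadcastable gates
`gate_h ⊙ gate_w`, which realize the two-dimensional gate `x_hw` as a
rank-one product — the only shape-consistent reading given that the gate
must multiply the full-resolution grouped input.

**CCIB output.** `x1 = x_group ⊙ σ(x_h) ⊙ σ(x_w) ⊙ gate_h ⊙ gate_w`. The
sigmoids apply to the raw pooled descriptors (no shared projection first).
All four factors lie in (0, 1), so `|x1| ≤ |x_group|` elementwise.

**SCB.** Three stacked same-padded, stride-1, width-preserving convolutions
with kernels 1, 5, 7 (in application order), then GELU.

**CSFA.** `x11 = softmax_c(mean_hw(GroupNorm(x1)))` and
`x22 = softmax_c(mean_hw(x2))`; the cross products
`x12 = x11 ⊗ x2` and `x21 = x22 ⊗ x1` (batched 1×C' by C'×HW matrix
products) form `weight = x12 + x21` and the output
`σ(weight) ⊙ x_group`. The GroupNorm uses one group per channel
(per-channel spatial normalization, identity affine initialization,
ε = 1e-5). Note the raw `x1` — not its normalized copy — enters the `x21`
product; the normalized copy only feeds the channel-softmax descriptor.
This is the reading under which a constant-branch input `x1 ≡ c1, x2 ≡ c2`
yields the closed form `σ(c1 + c2) ⊙ x_group`, which the tests pin down.

**Ablation wiring.** All branch parameters are always constructed (identical
weight streams across flag settings); the flags rewire only the forward pass:
disabling the star structure removes exactly the `gate_h ⊙ gate_w` factors;
disabling CSFA fuses with `σ(x1 + x2) ⊙ x_group`; a CCIB-only block uses
`σ(x1)`, and an SCB-only block gates with its own channel-pooled
softmax-weighted map `σ(x22 ⊗ x2)`. CSFA requires both branches; at least
one branch must remain enabled.

## The backbone

Input stream: two 3×3 convolutions (the first stride-2 — the stem carries
one of the four resolution reductions) followed by three Base Blocks
(`conv3×3 → BatchNorm → GELU → maxpool 2×2 stride 2 → DropPath`). Trunk:
four residual StarMA Blocks at constant width and 14×14 resolution, each
computing `x_a = Conv3×3(GELU(StarMA(BN(Conv3×3(Conv3×3(x))))))` (a single
BatchNorm after the two stacked convolutions, as written),
`x_attn = DropPath(x_a) + x`, a 1×1-convolution MLP with expansion ratio 4,
and `GELU(DropPath(M) + x_attn)`. Output stream: a Normal Block (Base Block
without pooling or DropPath, width-preserving), a 3×3 stride-2 convolution
(14→7), a 1×1 convolution, BatchNorm, GELU, global average pooling and a
linear head.

**Width calibration.** Channel widths are not individually published; only
the aggregate budget (47.5M parameters, 18.11G MACs at 224²) constrains
them. The reference widths — stem (80, 128), stages (240, 352, 512), trunk
512, MLP ratio 4, output (784, 984), binary head — were found by a one-time
integer search over group-multiple widths whose analytic parameter/MAC
formulas land inside the printed rounding bands, then frozen. The profiler
reproduces 47.508M / 18.1101G for this configuration.

**Width multiplier.** Every width field is scaled and rounded to the nearest
multiple of `G` (minimum `G`); a multiplier of 0.5 reproduces the
channel-halved variant with a parameter ratio of ≈4.0 (quadratic width
scaling; affine normalization terms and the head deviate slightly).

## Numerical substrate

All layers run on a small reverse-mode automatic-differentiation engine over
NumPy arrays (im2col convolutions backed by BLAS matrix products; exact-erf
GELU; fused softmax cross-entropy). Gradients of every primitive are checked
against float64 central differences in the test suite. Default compute dtype
is float32; weight initialization is truncated normal (σ = 0.02, clipped at
±2σ) driven by a single construction-order-stable generator seeded from the
config, so identical seeds give bit-identical models. Checkpoints are `.npz`
archives of the flattened state dict plus the JSON-encoded config and its
hash.

**BatchNorm at small scale.** With 15 optimizer steps per epoch the
exponentially averaged running statistics (momentum 0.1) lag the fast-moving
features, making evaluation-mode accuracy noisy. Before each validation pass
and final checkpoint the trainer therefore recomputes the running statistics
as a plain cumulative average of batch statistics over the training set
("precise BN"). This affects only the stored statistics, never the weights.

## Complexity accounting

"FLOPs" columns in the model-complexity tables of this literature are
multiply-accumulate counts: one fused multiply-add is one unit, and only
convolution and fully connected layers are counted (normalization,
activations, pooling, softmax and the small attention matrix products are
excluded). This is the convention under which standard VGG19 (143.67M,
19.63G) and ResNet34 (21.80M → "22M", 3.66G → "3.7G") land on their printed
budgets at 224² with 1000-class heads, which is how the accountant is
cross-checked; the two reference models are instantiated zero-weighted for
this purpose only. Convolutions inside the attention block run on the
group-folded batch, so the profiler scales each layer's count by its local
batch dimension; totals are reported per single input.

The channel-coupling index reported alongside attention analyses has no
published formula; the package provides a documented proxy — the mean
absolute off-diagonal Pearson correlation between channels' attention-weight
trajectories across samples, with the per-sample channel-weight variance as
companion statistic — and tests only the proxy's behaviour (1.0 for
perfectly coupled channels, →0 for independent ones), never a numeric
target.

## Synthetic data

The generator emulates the geometry of lesion-classification datasets: each
image is a smooth textured background (Gaussian-filtered noise, σ = 6 px,
amplitude 0.05 around level 0.35) carrying one elliptical lesion with
class-specific semi-major axis, eccentricity, additive contrast (default
0.35) and internal sinusoidal texture, corrupted by multiplicative speckle
(variance 0.01, ultrasound-like) and additive Gaussian noise (σ = 0.02).
Lesion masks are stored with every image so localization checks have ground
truth. The default three classes use semi-major axes (5–8), (11–14),
(18–21) px with eccentricity in (0.75, 1), making the lesion *area* bands
(≈59–201, 285–616, 763–1385 px²) disjoint: the classes are separable by
lesion size alone, by construction. (An earlier wider eccentricity range let
adjacent area bands overlap, which a globally pooled classifier cannot
resolve; the ranges were narrowed once to restore the construction
guarantee.) Splits are per-class stratified shuffle-splits with
`round(fraction·n)` validation/test sizes and the remainder to train;
default ratios 7:1.5:1.5.

What the generator does **not** emulate: anatomical context, multiple or
overlapping lesions, acquisition artifacts (acoustic shadowing, beam
inhomogeneity), inter-device variation, or label noise. Passing the
benchmark therefore shows that the architecture, gradients, training loop
and interpretability path work end to end on a size-separable task — it is
no evidence about accuracy on real medical data.

## The lesion benchmark

`starma.experiments.lesion_benchmark` trains the quarter-width network on
64×64 inputs — 240 training and 60 held-out images, batch 16, 15 epochs —
and reports held-out accuracy plus the fraction of test images whose
Grad-CAM heatmap (taken at the last StarMA block, the default target layer)
is hotter inside the lesion mask than outside. The benchmark's optimizer
setting is AdamW with learning rate 5e-4: the full-scale protocol
(learning rate 1e-5, 100 epochs) is far from convergence within a 15-epoch
budget, so the short-schedule rate is the package's own choice, picked as
the largest setting that converges smoothly at this scale. Problem sizes
were chosen to keep the whole benchmark within minutes on one CPU.

## Known limitations

* CPU-only and unoptimized for large inputs; full-resolution training at
  224² is possible but slow (the 18G-MAC forward pass takes seconds per
  image in NumPy).
* Max-pooling backward supports the non-overlapping windows the backbone
  uses; the overlapping 3×3-stride-2 pooling of the ResNet34 reference is
  forward-profiled only.
* The training protocol defaults mirror the published settings (AdamW — the
  settings table's "Adam" is kept as an option — learning rate 1e-5, batch
  16, 100 epochs, best-validation checkpointing, bilinear 224² resize,
  scale-to-[0,1] preprocessing); none of the published dataset accuracies
  are reproduced or claimed here, since they require the external datasets
  and GPU-scale training.
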