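# Methods

`tamunet` implements a liver CT semantic-segmentation pipeline around
TAMU-Net — a U-Net whose encoder stages are re-weighted by multi-scale
convolutional attention (MSCA), whose bottleneck is an atrous spatial
pyramid pooling (ASPP) block, and whose skip connections are replaced by a
channel-wise cross-fusion transformer (CCT) with a channel-wise
cross-attention (CCA) decoder gate. Everything runs on synthetic CT phantoms
so the full pipeline is testable on one CPU without any data download.

## Numerical engine

No GPU deep-learning framework is used: `tamunet.nn` is a compact
reverse-mode autodiff engine on float32 numpy arrays. Convolutions
(strided/dilated/grouped) are lowered to BLAS matrix multiplication via
im2col with hand-written adjoints; pointwise (1×1) and depth-wise kernels
take dedicated fast paths; batch/instance normalization and softmax are
fused primitives with analytic backwards. Every hand-written adjoint is
checked against central finite differences in the test-suite (float64
objective accumulation, eps = 1e-2, relative tolerance 1e-2 — appropriate
for a float32 forward). Parameter initialization is Kaiming-normal for
convolutions and uniform ±1/√fan_in for linear layers, seeded through a
single generator per model.

## Architecture

*Baseline U-Net.* Four encoder stages of two 3×3 conv + BN + ReLU
(widths 64-128-256-512, convs bias-free under BN), 2×2 max-pooling,
a 1024-wide bottleneck, kernel-2/stride-2 transposed-convolution
upsampling, skip concatenation, and a 1×1 conv + sigmoid head. With one
input channel this totals 31,036,481 trainable parameters (31.04 M).

*MSCA.* A₀ = 5×5 depth-wise conv of the stage output; three separable
depth-wise branches (1×k then k×1, k ∈ {7, 11, 21}) of A₀; the 1×1
convolution of A₀+A₁+A₂+A₃ is the attention map, applied by Hadamard
product. No squashing is applied to the attention map — the block is a
learned linear re-weighting, which is why an untrained float32 model can
saturate its sigmoid head; training normalizes this immediately. The skip
path and the pooling path both take the MSCA output.

*ASPP.* Five branches at the bottleneck width (1×1; 3×3 dilated at 6/12/18,
the DeepLabv3+ defaults, config-exposed since only "distinct rates" is
specified; global-average-pool → 1×1 → bilinear restore), concatenated to
5C′ channels, batch-normalized, then projected by a 1×1 convolution.

*CCT/CCA.* The four skips are patch-embedded by average pooling (patch
sizes P, P/2, P/4, P/8; parameter-free, the simplest faithful reading of
"reshaped and flattened") into token sets with a common token count d and
channel widths 64/128/256/512 (ΣC = 960 at full width). Attention runs over
the channel axis: per scale and head, the similarity Qᵢᵀ K is scaled by
**ΣC exactly as specified (not √ΣC)** — a deliberate divergence from
common attention practice — instance-normalized, softmaxed over the ΣC
axis, and applied to Vᵀ. The per-head projections are stored stacked so all
heads use one GEMM; K/V projections of the concatenated tokens are shared
across scales. N = 4 head outputs are averaged. Each layer is pre-norm with
true residuals — uᵢ = Tᵢ + MCAᵢ(LN(T), LN(T_Σ)); Tᵢ ← uᵢ + MLPᵢ(LN(uᵢ)) —
because the source description states its normalizations are present but
omitted from the printed update equations, and the layer is not stably
trainable without them. The MLP has one hidden layer (×4 expansion, GELU —
unspecified upstream, standard transformer default); the block repeats
L = 4 times. Tokens are reshaped to the patch grid, bilinearly upsampled
and 3×3-convolved back to skip resolution. The CCA gate is
sigmoid(L₁·relu(η(O)) + L₂·relu(η(D))) with η = spatial global mean and two
independent full-width linear maps (no channel reduction); the placement of
the ReLU is interpretive — the operator is declared but not placed upstream.

Ablation variants (TAU/TMU/AMU-Net) are build-time flags; all flags off is
bit-identical to the baseline given the same weights.

## Synthetic phantoms

Each case is a (Z, Y, X) HU volume: background ≈ N(10, 12²) HU, a liver as
an ellipsoid whose boundary radius is perturbed by a smoothed random field
(amplitude 12 % of local radius) with voxels ≈ N(55, 6²) HU (the
parenchymal 40–70 HU band), 3 distractor ellipsoids drawn from the same HU
band (clipped to never overlap the liver, creating same-intensity
ambiguity without label noise), two air (−950 HU) and two bone (+700 HU)
blobs, additive N(0, 8²) HU noise, and a liver-free band (15 % of slices,
split top/bottom) that exercises the training-set slice filter. Default
volume 64×128×128 at 2.5/1.5/1.5 mm; `default_phantom_config` scales the
liver semiaxes to 30/33/38 % of the Z/Y/X extent so smaller phantoms keep
the same anatomy-to-field-of-view proportions. All randomness flows from
one seed; regeneration is bit-identical. The phantoms deliberately omit
lesions, contrast phases and scanner artifacts, so passing tests show the
pipeline's mechanics and learnability — not clinical performance.

## Preprocessing

HU windowed to [−400, 400], mapped linearly to uint8 (the 127.5 midpoint
rounds half-away-from-zero, so 0 HU → 128 — the rounding rule is fixed here
because it is unspecified upstream); bilinear image / nearest mask resize to
the model input size; case-wise 8:1:1 split with floor/floor/remainder
(the only rule reproducing 104/13/14 from 131 cases), seeded shuffle within
each source; liver-free slices dropped from the training set only; online
augmentation (rotation ±15°, scale 0.9–1.1, drawn fresh per load, fill 0)
applied to training samples only. In-plane resampling is subsumed by the
2D resize; Z spacing is carried through for the 3D metrics.

## Training

BCE loss (probabilities clamped to [1e-7, 1−1e-7]), Adam, batch 4,
per-epoch cosine annealing from 1e-4 to 1e-7 (per-epoch, not per-step —
only epochs are specified), per-epoch validation Dice/IoU on un-augmented
samples, best-validation-Dice checkpoint retained. Prediction threshold
0.5 (CLI-exposed).

## Metrics

2D scores from pixel confusion counts; MIoU is the two-class mean, MPA the
mean of per-class pixel accuracies. Degenerate denominators: empty
prediction *and* empty reference score 1 (agreement on absence); any other
empty case scores 0. 3D: slice predictions are re-stacked by Z (complete,
unique coverage enforced). VOE is implemented as 1 − IOU: the printed
subtraction-style formula contradicts every published results row, which
satisfies the complement identity exactly. RVD is kept signed and reported
as a fraction (the published tables print fractions despite a ×100 % in the
defining formula). Surfaces are 6-connectivity boundary voxels (array
borders count as background); distances are Euclidean nearest-surface via
distance transform (the all-pairs brute force is retained as the test
oracle), in voxel units by default, mm when spacing is requested — the
published tables' units are ambiguous, so a flag chooses.

## Desk-scale learning study

`tamunet.experiments` runs the pipeline end-to-end: a base-width-16
TAMU-Net trained 10 epochs on 200 liver-containing phantom slices
(batch 4) must reach mean per-slice Dice > 0.80 on a held-out phantom,
averaged over 3 seeds; and one memorized batch of 4 must be driven below
0.05 BCE in 200 Adam steps at lr 1e-3 (the standard Adam default; the
probe's rate is not specified upstream). The study runs at 48×48 slice
resolution — chosen as the smallest input at which the channel-transformer
token grid is still informative: P must be divisible by 8, so at 32×32 the
grid is capped at 4×4 (16 tokens) and the skip-connection path cannot
carry enough spatial detail (the study then plateaus near Dice 0.5), while
48×48 gives a 6×6 grid (36 tokens). Slices come from full-size 64×128×128
phantoms, so the liver-to-distractor size ratio matches the default
anatomy.

Short low-learning-rate runs of segmentation networks are prone to
collapsing to the background class; three standard measures make the study
converge reliably across seeds without touching the stated conditions:
the MSCA projection bias starts at 1 (the multiplicative attention begins
as a near-identity gate); the head bias starts at the logit of the
foreground pixel prior, so the model begins at the class base rate instead
of spending its early, most-plastic steps un-collapsing; and the 10-epoch
run performs the first 10 epochs of the full 50-epoch cosine schedule
(`TrainConfig.anneal_epochs`) rather than compressing the entire anneal
into 10 epochs, which would spend the second half of the run at a nearly
zero learning rate.

## Known limitations

- Pure-numpy training is practical only at reduced width/resolution; the
  full-width 256×256 model is built and forward-checked but not trained in
  the test-suite.
- The "multi-scale input strategy" mentioned only in the source abstract has
  no specified mechanism and is not implemented.
- BN uses biased batch variance for both normalization and running
  statistics; eval-mode behaviour is standard.
- FLOP counting is not provided (convention-dependent); parameter counting
  is exact.
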