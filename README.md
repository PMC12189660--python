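# tamunet

Liver semantic segmentation in abdominal CT with **TAMU-Net** — a U-Net
whose encoder is re-weighted by multi-scale convolutional attention (MSCA),
whose bottleneck is atrous spatial pyramid pooling (ASPP), and whose skip
connections are replaced by a channel-wise cross-fusion transformer (CCT)
with a channel-wise cross-attention gate (CCA) — together with the plain
U-Net baseline, the full 2D/3D evaluation battery, and a synthetic CT
phantom generator so that the complete pipeline (generate → preprocess →
split → train → evaluate in 2D and 3D → visualize) runs end-to-end on one
CPU with no external data.

It is aimed at researchers who want a dependency-light, fully inspectable
reference implementation of this architecture family: every layer — from
dilated and separable depth-wise convolutions up to the channel
transformer — is written on a small numpy autodiff engine (`tamunet.nn`)
and verified against independent oracles (dense-kernel equivalents,
finite differences, brute-force matrix computations).

## The model

With encoder features `F_En` and decoder features `F_Dm`:

    F_En  = MSCA(Conv(F_En-1))            n = 1..4   (widths 64,128,256,512)
    F_E5  = ASPP(Conv(F_E4))                         (bottleneck, 1024)
    F_Dm  = Concat(CCA(CCT(F_En)), ConvT(F_Dm+1))
    ŷ     = sigmoid(Conv1x1(F_D1))

MSCA: `Out = Conv1x1(A0 + Σk SDW_k(A0)) ⊙ F` with a 5×5 depth-wise `A0`
and separable depth-wise branches k ∈ {7, 11, 21}. ASPP: five parallel
branches (1×1; 3×3 at dilation 6/12/18; global-average pooling restored
bilinearly), concatenated, batch-normalized, projected. CCT: per-scale skip
tokens `T_i` (patch-embedded, channel width preserved) attend over the
channel axis against their concatenation `T_Σ`:
`CA_i = softmax(IN(Q_iᵀK / C_Σ)) Vᵀ`, N = 4 heads averaged, residual MLP,
L = 4 layers. CCA gates each reconstructed skip channel-wise:
`Ô = sigmoid(L1 relu(η(O)) + L2 relu(η(D))) ⊙ O` with η = global average
pooling. Training uses per-pixel binary cross-entropy and Adam under
per-epoch cosine annealing from 1e-4 to 1e-7 (batch 4, 50 epochs at full
scale). Metrics: precision, recall, Dice, per-class IoU, MIoU, MPA,
accuracy in 2D; DICE, IOU, VOE = 1−IOU, signed RVD, and the symmetric
surface distances ASD/MSD on Z-stacked volumes in 3D.

All three additions are independent build flags, so the ablation variants
(TAU-Net, TMU-Net, AMU-Net) and the plain baseline come from the same
assembly. The baseline U-Net builds to 31.04 M trainable parameters.

## Worked example

A miniature study from the shell (five phantom cases, one training epoch of
a small U-Net — enough to watch the whole pipeline move):

    tamunet phantom    --n-cases 5 --seed 7 --out work/phantoms --shape 12,32,32
    tamunet preprocess --cases work/phantoms/cases.csv --out work/slices --target-size 32
    tamunet split      --cases work/phantoms/cases.csv --out work/split.json --seed 7
    tamunet train      --data work/slices --split work/split.json --out work/run \
                       --arch unet --base-width 2 --epochs 1 --seed 7
    tamunet eval3d     --data work/slices --split work/split.json \
                       --checkpoint work/run/checkpoint.npz --out work/m3d.csv
    tamunet params     --arch unet

which ends with

    unet: 31,036,481 trainable parameters (31.04 M)

— the baseline's published parameter total. The Python API runs the real
desk-scale study (reduced TAMU-Net, base width 16, 10 epochs on 200
phantom slices at 48×48):

    >>> from tamunet.experiments import run_learning_study
    >>> res = run_learning_study(seed=1)
    >>> round(res["test_dice"], 3)
    0.868

i.e. mean per-slice Dice ≈ 0.86 on a held-out phantom after ten epochs —
what a correctly wired pipeline (windowing, filtering, augmentation, loss,
schedule, metrics) achieves on this synthetic task in a few CPU-minutes.

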