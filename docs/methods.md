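# Methods

## Model

The segmentation network is a standard U-Net over RGB inputs in [0, 1]:
`depth` encoder stages of (3×3 conv → batch-norm → ReLU) × 2 with 2×2
max-pooling between them, a bottleneck block, and a mirrored decoder using
learned 2×2 stride-2 transposed convolutions with skip concatenation.
Channel width doubles per stage, so `first_encoder_channels = 16` and
`depth = 4` give a 256-channel bottleneck; inputs must be divisible by
2^depth. The head is a 1×1 convolution to two class logits; the
foreground probability is the class-1 channel of a per-pixel softmax.
Convolutions inside blocks carry no bias (batch-norm cancels additive
constants — the bias gradient is exactly zero there); the head keeps its
bias. Weights are He-normal initialised from a seeded generator. Images
are used in [0, 1] without mean/std whitening — the synthetic data and
the loss are scale-consistent, and inference needs no stored statistics
beyond batch-norm's.

The network, backpropagation and SGD are implemented directly on NumPy
arrays (channels-last). Convolutions run as nine batched strided matmuls
(one per kernel tap) so BLAS operates on contiguous (W, C) panels without
an im2col copy; the input gradient is the convolution of the output
gradient with the spatially flipped, channel-transposed kernel; the
weight gradient uses full-width band GEMMs. Batch-norm and max-pool have
fused single-pass numba kernels for float32; every layer also has a
dtype-preserving NumPy path, which the test suite uses to check the whole
backward pass against float64 finite differences (median relative error
~1e-9) and to verify that the two paths agree to ~1e-4.

## Training objective

`L_seg` is 0.5 · Dice + 0.5 · cross-entropy. The published description
applies a mask elementwise to `L_seg`, which type-checks only for a
per-pixel loss; Dice is global. We therefore interpret masking as
*region restriction*: the cross-entropy is averaged over in-region pixels
and every Dice sum runs over the region only. This reduces exactly to the
plain full-image loss when the region is all-ones, which is the property
the equations rely on. Probabilities are clamped at 1e-7 inside logs;
Dice smoothing uses ε = 1e-5. An all-zero region supervises nothing and
contributes 0 (with a logged warning). The 0.5/0.5 Dice/CE mix is a
configurable default; the source description fixes only "linear
combination".

For one copy-paste pair, the synthetic losses weight the labeled-origin
region at 1 and the unlabeled-origin region at α:

    L_in  = L_seg(Q_in,  Y_in,  M) + α · L_seg(Q_in,  Y_in,  1−M)
    L_out = L_seg(Q_out, Y_out, 1−M) + α · L_seg(Q_out, Y_out, M)

and the fused total is `L_in + L_out + γ(L_i + L_j)` with the direct
losses computed from the *student's* predictions on the raw labeled
images. (The published pseudo-code writes those two terms with the
pre-trained weights Θp, but the accompanying equations use Θs, and the
gradient step is taken in Θs — only the Θs reading is self-consistent, so
that is what is implemented.) γ = 0 recovers the pure-BCP objective
exactly; the trainer's per-iteration log makes this reduction testable.

Gradients of the objective with respect to the foreground probability are
analytic (the Dice quotient rule plus clamped binary cross-entropy) and
are chained through the two-class softmax as dL/dz₁ = dL/dp · p(1−p).

## Copy-paste mechanics

The mask M is a single axis-aligned rectangle of
⌊ratio·H⌋ × ⌊ratio·W⌋ ones at a uniformly random position. "Mask size
2/3 of the input image" is read per spatial dimension (the copied region
is 4/9 of the pixels), matching the reference convention of the BCP
family; the ratio is configurable. Within a half-batch of 2k images, a
seeded shuffle is split into halves (first k are i/p, last k are j/q),
which enforces i ≠ j and p ≠ q while using every image once; one M is
shared by the X_in and X_out of a pair. Pseudo-labels threshold the
teacher's foreground probability strictly at 0.5 and are produced in
inference mode — no gradient path exists through the teacher by
construction (the framework only differentiates through an explicit
backward call on the student). When the labeled pool is smaller than the
half-batch (unavoidable at small label ratios), batch indices are drawn
with replacement; pair positions remain distinct.

## Training procedure

Stage 1 pre-trains Θp by plain supervised learning on the labeled subset
(batches of `batch_labeled` images, mean full-image loss). An optional
synthetic mode instead composes copy-paste pairs *among labeled images*
(real ground truth on both sides), provided to reproduce the comparison
between the two initialisation strategies; direct labeled training is the
default because it performed better in the original study. Stage 2
initialises Θt = Θs = Θp and per iteration: builds synthetic batches,
forwards the student on X_in, X_out, X_i, X_j as one concatenated batch
(batch-norm statistics therefore pool over all four groups), applies one
SGD step (constant learning rate by default — no schedule is specified in
the source; a polynomial decay is available behind `poly_lr_decay`), then
EMA-updates the teacher, including batch-norm running statistics.

"Best" checkpoint selection means highest validation Dice, evaluated
every `eval_every` iterations and at the final iteration; validation uses
the student, which is also the returned model. Without a validation
split the final weights are returned. Checkpoints are zip archives of
raw `.npy` arrays plus a JSON header (format version, architecture,
iteration, validation Dice) with fixed timestamps, so identical states
produce byte-identical files.

EMA with λ ∈ [0, 1] includes all buffers; k repeated updates against a
frozen student follow the closed form λᵏθ₀ + (1−λᵏ)θs, which the tests
verify to 1e-10 on float64 state (float32 accumulation noise would mask
the algebra at that tolerance).

## Synthetic data

The generator emulates lesion-centred skin patches: a per-channel uniform
base tone (R 0.45–0.95, G 0.30–0.80, B 0.22–0.70 — deliberately wide to
cover diverse skin tones), a linear luminance gradient of strength 0.25
in a random direction (the cheapest model of varied lighting), 0–3
lesions per image, and Gaussian sensor noise (σ = 0.02). Lesions are
rotated ellipses (aspect 0.6–1.0) whose boundary radius is modulated by
three low-frequency harmonics (amplitudes up to 0.15), giving irregular
but simply connected shapes; their color is the local skin tone shifted
redward (ΔR +0.02…+0.18, ΔG/ΔB −0.30…−0.06). Lesion color is applied
only to pixels strictly inside the support, so the ground-truth mask is
the exact union of lesion supports — no soft edge can leak foreground.
Rasterisation tests pixel centers (pixel (r, c) covers [r, r+1) × [c,
c+1)). What this generator does *not* model: texture (pores, hair),
specular highlights, camera compression, ambiguous lesion boundaries, or
annotation noise. Passing tests therefore demonstrate that the training
machinery behaves as specified, not that any particular Dice level
transfers to clinical images.

For datasets annotated with detection boxes only, ellipse pseudo ground
truth is the filled axis-aligned ellipse inscribed in each box (it passes
through the midpoints of all four sides). A textual description of this
construction could be read as "circles" through the side midpoints, but
such circles exist only for square boxes; the inscribed-ellipse reading
is the one consistent with the accompanying figure and is adopted. A
1-pixel box degenerates to a single-pixel mask.

## Evaluation and benchmark

Dice and Jaccard are computed per image on thresholded predictions and
averaged over the set (per-image means, not pooled pixels); two empty
masks score 1.0. Jaccard = Dice/(2 − Dice) holds per pair and is asserted
to 1e-9.

The bundled desk-scale benchmark generates 250 images at 64 px (200
train / 50 validation, every patch containing 1–3 lesions, mirroring
lesion-centred cropping), labels 5% of the training set (10 images), and
trains an 8-channel U-Net for 300 pre-training plus 300 semi-supervised
iterations per method and seed. These sizes are the package's scaled-down
analogue of the full-resolution protocol (256 px, 16+ channels, 10k/30k
iterations), which remains reachable purely through configuration. The
expected ordering — fused objective ≥ pre-training only, and ≥ the γ=0
BCP baseline in most seeds — is asserted over 3 seeds; individual seeds
are noisy at this scale, which is why the check is stated as 2-of-3.

## Known limitations

- Single-device, single-precision training only; no data augmentation
  beyond copy-paste itself.
- Determinism is guaranteed per machine/BLAS build, not across platforms.
- The loss treats exactly-saturated probabilities as constants (clamped),
  so gradients vanish there; with lr 0.01 and batch-norm this has not
  been observed to stall training.
- `run_comparison` retrains from scratch per row; sweeps over many
  gammas/channels are CPU-hungry.
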