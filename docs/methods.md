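# Methods

## Problem and model

`spinediff` performs binary segmentation of 2-D sagittal spine-like images by
treating the mask as the object of a conditional denoising diffusion process.
Two networks cooperate:

1. a **conditional U-Net** that maps the raw image `b` to a prior
   probability mask `f(b) ∈ [0,1]^{H×W}` (a conventional discriminative
   segmenter), and
2. a **diffusion U-Net** `Φ_θ(x_t, t, ·)` that predicts the Gaussian noise
   component of a corrupted mask `x_t`.

The forward corruption of a ground-truth mask `x0` is shifted by the prior:

    x_t = √ᾱ_t · x0 + √(1−ᾱ_t) · f(b) + √(1−ᾱ_t) · ε,   ε ~ N(0, I),

with `α_t = 1 − β_t` and `ᾱ_t = ∏_{s≤t} α_s`.  Reverse sampling starts from
`x_T ~ N(0, I)` and iterates

    x_{t−1} = (x_t − (1−α_t)/√(1−ᾱ_t) · ε̂) / √α_t + σ_t z,

with `z = 0` at `t = 1` and `σ_t² = (1−ᾱ_{t−1})(1−α_t)/(1−ᾱ_t)` (the
posterior variance, fixed rather than learned).  The final grid is clipped to
[0,1]; several independent chains are averaged (ensemble) and thresholded at
0.5.

The per-step single-transition kernel with a per-step prior shift does not
algebraically telescope to this marginal; the marginal form above is treated
as the definition of the forward process and the single-step form as
schematic.  `posterior_mean` (the forward posterior's mean) is implemented
and tested independently but the sampler uses the noise-prediction update
above.

## Loss

Training minimises, per uniformly drawn `t` and noise draw `ε`:

* `L_simple = mean((ε − ε̂)²)` — noise-prediction MSE;
* `L_BCE` — binary cross-entropy between `x0` and the implied clean-mask
  estimate `x̂0 = (x_t − √(1−ᾱ_t) f(b) − √(1−ᾱ_t) ε̂)/√ᾱ_t`, hard-clamped to
  `[10⁻⁶, 1−10⁻⁶]`.  Applying BCE to the raw noise pair is undefined outside
  [0,1], so the clean-mask form is used;
* `L_total = L_simple + L_BCE` (unit weights), plus an auxiliary BCE between
  `f(b)` and `x0` so the conditional network is trained jointly as a
  discriminative segmenter (gradients also reach it through the shift term
  inside `x_t`).

## Conditioning

The denoiser input is the channel concatenation `[x_t, X, f(b)]`, where `X`
is the MSFM-refined image (the raw image when MSFM is disabled).  The prior
is computed once per image during sampling, not per step.  Timestep
conditioning uses a sinusoidal embedding passed through a two-layer MLP and
added as a per-channel bias in every residual block.

## MSFM

Three same-padded, bias-free convolution branches (3×3, 5×5, 7×7) over the
input; element-sum → global average pooling → fully connected layer with ELU
and running-statistics normalisation to a `d`-vector (`d = max(C/4, 4)`); three
learned `C×d` logit matrices produce a per-channel three-way softmax
(`a_n + b_n + c_n = 1`, overflow-guarded by max-subtraction); output is the
per-channel convex combination of the branches.  It is applied to the raw
image before the conditional U-Net, and the same instance's output is the
denoiser's image-feature channel.  The branch kernels use near-identity
initialisation (centre delta plus damped random taps): a module inserted in
front of an untrained encoder should start as a mild perturbation of its
input rather than a random filter, which measurably shortens convergence of
the downstream segmenter without changing what the module can learn.

## NSA

At each encoder level of the diffusion U-Net: a fine branch (3×3 by default,
5×5 selectable) and a spatial branch (depthwise 7×7, dilation 3, padding 9,
then pointwise projection), both to C/2 channels and bias-free.  Their
elementwise product is reduced to channelwise mean and max maps, concatenated,
projected by a 7×7 convolution back to C channels and squashed by a sigmoid
into the gate `T ∈ (0,1)`.  `T` is split into two C/2 halves aligned with the
branches; `V̄ = F⊙T_F + S⊙T_S` is tiled to C channels and multiplied with the
block input (`V = V̄⊙X`), so the block is shape-preserving and vanishes where
its input vanishes.  Disabling NSA makes the block the identity.

## Networks

Plain residual U-Nets with GroupNorm/SiLU, average-pool downsampling,
nearest-neighbour upsampling, and pad-and-crop so arbitrary spatial sizes
work.  Presets: `tiny` (widths 8/16, one downsampling, ~36k parameters) for
tests and scaled studies; `full` (widths 64/128/256/512) for full-scale
runs.  Where batch statistics are degenerate at batch size 1, normalisation
over running statistics (MSFM's compression layer) treats the statistics as
constants on the tape; a statistics-free test mode gives unit tests
closed-form expectations.

## Schedule

Linear `β` from 1e-4 to 0.02 (the convention this family of models
inherits; the source formulation does not state its schedule), `T = 1000`
default, `T = 100` for scaled runs.  `ᾱ_0 := 1` so `t = 1` formulas are
well-defined; the `t = 1` reverse step is deterministic.  Note that with
the endpoints fixed, small `T` leaves `ᾱ_T` well above zero (≈0.36 at
`T = 100`), so `x_T` is not pure noise relative to the training marginal;
the strongly conditioned denoiser tolerates this at `T = 100`, but runs at
much smaller `T` should scale `beta_end` up accordingly (both endpoints are
config fields).

## Training protocol

Adam, batch size 1, maximum 9000 iterations, early stopping when a
deterministic validation objective (hybrid loss at fixed `(t, ε)` draws)
stops decreasing — learning rate 1e-4 at full scale.  An exponential moving
average of the weights (decay 0.999, warm-up ramp) is kept during training
and used for inference: single-sample optimisation leaves the raw weights
oscillating, and the averaged denoiser samples markedly cleaner masks.
Residual blocks zero-initialise their closing convolution (each block
starts as its skip path, with the timestep bias applied at the block
output), which removes most initialisation-to-initialisation spread in
convergence speed.  Dynamic augmentation:
rotation uniform in ±30°, shifts of 1–5% of the frame, coarse elastic
deformation (8-px grid, bilinear upsampling) and gamma contrast on the image
only; the geometric transform is shared by image and mask and the mask is
re-binarised; the augmentation stream is seeded (default 35).

## Synthetic data

The generator emulates sagittal spine frames: a 160×64 canvas (high aspect
ratio), five superellipse vertebra bodies with posterior lobes stacked with
disk gaps, smooth random coordinate warping (shape deformation), foreground
0.675 vs background 0.325 by default (`bg_contrast = 0.35`), smooth background
texture, Gaussian boundary blur (σ = 0.8) and pixel noise (σ = 0.03).  Modes:
`ct-like` (crisp), `mr-like` (dimmed lobes, more blur), `xray-like` (heavy
blur, bright streak artifacts).  Geometry constants (11% vertical margin,
0.18-width bodies) keep the column inside the frame under the full
augmentation range.  What it does **not** emulate: real anatomy and texture
statistics, annotation noise, multi-slice context, intensity calibration of
any actual modality — passing the scaled study shows the pipeline learns and
samples correctly, not that it reaches clinical accuracy.

## Scaled-down study

The end-to-end checks train the `tiny` preset on 200 generated pairs
(T = 100, lr 1e-3, batch 1, early stopping within a 1200-step cap — 1e-3
rather than 1e-4 because at ~36k parameters and ~1000 single-sample steps
the full-scale rate is far from convergence; this is a standard size-scaled
choice) and score ensemble-of-3 predictions on 20 held-out images.  Dynamic
augmentation is off in this study: with 200 pairs and ~1200 steps each pair
is seen only a few times, so overfitting protection is unnecessary while the
added input variability roughly doubles the steps needed to converge; the
full-scale defaults keep augmentation on.  The ablation comparison (base
conditional DDPM vs +MSFM vs +NSA) runs each configuration under the
identical protocol on identical data and seeds; because per-image Dice
varies by a few hundredths at this scale, the direction comparison carries
a declared noise allowance of 0.05 Dice; to keep the study within a
one-CPU budget the direction comparison scores six held-out images while
the headline score uses twenty (both ensemble-of-3).  The
ensemble property check compares the across-seed variance of per-image Dice
under ensemble-of-5 versus single-sample inference on two held-out images
and five sampling seeds.

## Numerical choices

* Network arithmetic in float32; schedule/diffusion closed forms in float64.
* BCE clamp δ = 1e-6 (hard clamp; gradient is zero where clamped — the MSE
  term still provides signal there).
* Softmax and sigmoid computed with max-subtraction / stable forms.
* Binarisation threshold 0.5; both-masks-empty convention: Dice = IoU = 1.
* Ensemble default 5; scaled studies use 3 (the criterion's value).
* All randomness flows through explicitly seeded NumPy generators; identical
  seeds reproduce losses and sampled masks bit-for-bit.

## Known limitations

* Binary segmentation only (like the source formulation); no multi-class.
* No DDIM-style acceleration: sampling costs T denoiser passes per chain.
* CPU-only: the `full` preset is instantiable but impractical to train here.
* The learned-variance option for σ_t is not implemented (fixed posterior
  variance).
* Real-data readers (PNG/TIFF pairs, NIfTI slices) are provided but no real
  dataset ships with the package.
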