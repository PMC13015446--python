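# Methods

## The denoising model

Let `y_k = x + e_k`, `k = 1…n`, be co-registered noisy repetitions of an
unknown image `x`, with zero-mean noise `e_k` independent across
repetitions.  The package trains a convolutional denoiser `f` in *residual*
form: the network predicts `target − input`, and restoration adds the
prediction back to the input (`d = y + f(y)`).  The training target is the
repetition average `mean(y)` at iteration 1 and the previous iteration's
denoised average afterwards; at each iteration every repetition is denoised
and the results are averaged into the iteration's output.

The arithmetic behind the iteration count: the iteration-1 target has noise
variance `sigma^2/n`; if the trained network matches the target's quality
while keeping independent errors across repetitions, averaging the `n`
denoised repetitions yields variance `sigma^2/n^2`, and iteration `i`
yields `sigma^2/n^(i+1)`.  The package verifies this law empirically with
oracle denoisers (below).  Defaults follow the recommendation of two
iterations for `n = 2` and one iteration for `n > 2`; in practice later
iterations trade noise for smoothness, so the uMSE stopping criterion is
provided for data without ground truth.

Noise-to-noise training (`noise2noise_run`) and supervised training against
a clean reference (`supervised_run`) are implemented as baselines with the
same block/standardization machinery.  For `n > 2` the noise-to-noise
pairing is cyclic (`y_k → y_(k+1 mod n)`); only the mutual `n = 2` pairing
has an external precedent, so the cyclic rule is this package's choice.

## Network and training

The denoiser is a "modified U-Net": `depth` 3×3×3 same-padded convolutions
at full resolution, ReLU after every layer except the final linear
convolution to `output_channels` (the residual head).  Decoder-half layer
`j` receives the concatenation of the previous output with the output of
mirrored encoder layer `depth−2−j`.  There is no pooling or up-sampling, so
the receptive field is `2·depth+1` voxels per axis.  Two reference
configurations are provided: depth 18 / 64 channels for single-channel
structural volumes, and depth 10 / 192 channels with batch normalization
before every convolution for multi-channel diffusion volumes.  Any layout
preserving shape and the residual head satisfies the package's contracts;
tests do not depend on the specific skip wiring.

Implementation notes (all numpy, float32):

- Convolutions are computed as 27 shift-and-matmul accumulations so the
  inner loop is BLAS; backward passes reuse the same scheme.  Training is
  deterministic under the config seeds in single-threaded execution.
- Weights use He initialization; the residual head is **zero-initialized**
  by default (`zero_init_head=True`), so the untrained denoiser is the
  identity map.  Without this the first few hundred Adam steps are spent
  shrinking the random head's output toward zero before any denoising is
  learned — an unproductive plateau at these small training budgets.
- Optimization is Adam (moments 0.9/0.999, eps 1e-8), batch size 1, loss
  evaluated only inside the brain mask; blocks whose mask slice is empty
  are excluded from training.  MSE is the default for structural data,
  MAE for diffusion data (robustness to low-SNR outliers).
- The 80/20 train/validation split over blocks is re-drawn every epoch
  (Monte Carlo cross-validation); subject-level pretraining uses a single
  fixed 80/20 split over phantoms instead.
- Learning-rate defaults: pretraining runs two phases (1e-4 then 1e-5,
  configurable via `lr_phases`); fine-tuning uses a single small rate
  (1e-5 at scale; the desk-scale examples use 1e-3/1e-4 because the tiny
  networks and short schedules need larger steps).
- Warm start: iteration `i+1` resumes the weights of iteration `i`
  (`warm_start=True`); the flag re-initializes from the starting weights
  instead when disabled.
- Divergent (non-finite) training losses abort with
  `TrainingDivergenceError` rather than continuing silently.

Volumes are standardized per channel to the masked mean/std before entering
the network and un-standardized after; the same affine map applies to all
voxels.  Whole volumes are covered by the minimal block grid
(`k = ceil(extent/block)` per axis, origins evenly spaced from 0 to
`extent − block`, block extents clamped to the volume rather than padded)
and reassembled with overlap averaging, which is exact for consistent
blocks and seam-free for smooth residuals.

## Oracle denoisers

Three idealized denoisers stand in for the network in property tests:
`perfect_target` (returns the training target — the ideal CNN),
`matched_noise` (returns the truth plus fresh Gaussian noise matching the
target's residual variance — the "equal quality, independent noise"
premise), and `identity`.  They pin down the iteration arithmetic exactly:
the perfect-target oracle makes the repetition mean a fixed point; the
matched-noise oracle reproduces the `sigma^2/n^(i+1)` law within
Monte Carlo tolerance; the identity oracle collapses all modes to plain
averaging.

## Synthetic data

`make_structural_phantom` builds nested ellipsoidal compartments (outer
tissue ~100, deep shell ~160, inner cavity ~40, in arbitrary units) with
smooth Gaussian-filtered texture at ~10% of the dynamic range — enough
structure for edges, compartment contrast, and nontrivial SSIM, while
remaining fully deterministic per seed.  `make_tensor_phantom` adds a
per-voxel tensor field with an isotropic compartment (0.8 um^2/ms),
two coherent bundles (eigenvalues 1.7/0.3/0.3 um^2/ms along x and y), and a
curved/fanning ring of tangential directions; S0 = 100 inside the mask and
all tensors positive-definite.

`simulate_repetitions` adds noise at absolute scale `sigma × std(truth)`
over the mask (per channel): Gaussian additive, or Rician as the magnitude
of the complex signal with per-component std at that scale.  Default
condition levels: sigma 0.3 (mild) and 0.5 (heavy) for structural
experiments; corpus pretraining uses 0.5 for structural data and 0.1/0.3
for b=0/DWI channels (`noise2average.corpus`).  Residual misalignment is
emulated by applying a small random affine directly (translation,
per-axis rotation, left-right scaling) with trilinear resampling; the full
ranges (10 voxels, ±3°, scale 1.0–1.4) describe the raw repositioning
between repetitions, and `misalign_fraction` (default 0.1) scales the draw
down to the residual level that survives co-registration, since no
registration engine ships with the package.  `misalign=False` gives the
idealized equal-geometry case the oracle tests rely on.  What the generator
does **not** emulate: anatomy, k-space/coil effects, spatially varying
(g-factor) noise, motion artifacts beyond affine error.  Passing tests
therefore demonstrate the method's statistical mechanics, not clinical
image quality.

## Diffusion toolbox

DWI synthesis uses `S = S0·exp(−b·gᵀDg)` with `b` in s/mm² and `D` stored
in um²/ms (1 um²/ms = 1e-3 mm²/s; conversion internal, pinned by a
closed-form test).  The OLS fit solves `ln S = ln S0 − b·gᵀDg` against the
7-column design `[1, −b·gx², −b·gy², −b·gz², −2b·gxgy, −2b·gxgz, −2b·gygz]`
per masked voxel; nonpositive signals are clamped to `1e-6 ×` the median
b=0 signal before the log.  Fits are not clamped to positive-definiteness;
physically invalid voxels are left to the caller.  Eigenvalues are sorted
descending; FA = sqrt(3/2)·‖lambda − MD‖/‖lambda‖, AD = lambda1,
RD = (lambda2+lambda3)/2, MD = mean(lambda); V1's sign is unconstrained and
every comparison of eigenvector fields is antipodally invariant.

Scheme design uses the convention with factor-2 cross terms and no b or S0
column for the 6×6 condition-number matrix — the convention under which the
known six-direction optimum κ ≈ 1.3228 holds (a Mandel/sqrt-2 convention
gives different numbers).  `optimize_directions` runs Nelder-Mead from
random starts on the spherical angles and polishes the best candidates with
alternating Powell/Nelder-Mead rounds; 100 restarts reliably land within
5e-4 of the optimum in about a minute.  Nearest-direction subset selection
uses the antipodally invariant arc angle `min(theta, pi−theta)` and the
default acceptance threshold κ < 1.6; 12-direction sets are chosen by
minimal electrostatic energy `sum 1/|u_i−u_j| + 1/|u_i+u_j|` over pooled
pairs (directions only — b=0 volumes do not enter the energy).

## Metrics

All image comparisons standardize with shared parameters and apply
`v' = ((v−mu)/s + 3)/6`, placing intensities roughly in [0, 1].  MAE and
PSNR (`10·log10(1/MSE)`, peak 1, +inf sentinel for identical inputs) are
computed over masked voxels; SSIM is the masked mean of the volumetric
local SSIM map with a 3D Gaussian window (sigma 1.5, 11³ support,
C1 = 0.01², C2 = 0.03²), cross-checked against scikit-image.  SSIM windows
may straddle the mask boundary; values are sampled at masked centers.
SSIM is computed in 3D rather than slice-wise, a deliberate choice for
volumetric data.

The unsupervised MSE is defined here as

    uMSE = mean_mask((d − y*)²) − mean_mask((y1 − y2)²)/2

with `y*` an extra noisy repetition not used to produce `d` and `(y1, y2)`
a same-noise-level pair: under independent zero-mean noise the second term
is an unbiased noise-variance estimate and uMSE is an unbiased estimate of
`MSE(d, x)`.  Tests verify unbiasedness over 200 Monte Carlo draws, the
U-shape under increasing smoothing, and exact rank agreement with the true
MSE across denoising iterations — the properties that make it a usable
stopping criterion.

## Problem sizes and numerical choices

The test suite and examples use 48³–64³ phantoms, 100³ noise fields for
variance-law checks, tiny networks (depth 2–4, 4–8 channels) with
10–35-epoch schedules, and 100–120 optimizer restarts for the scheme
design; these sizes were chosen so every pipeline runs end to end on a
single CPU in minutes while leaving the statistical checks well-powered.
Population (ddof 0) standard deviations are used throughout standardization
for determinism; coordinates are 0-based half-open intervals; block-grid
origins round to the nearest integer on an even spacing.  Checkpoints are
numpy `.npz` archives carrying the architecture and seed; training logs are
CSV via pandas.

## Known limitations

- No registration: inputs are assumed co-registered; the simulator's
  residual-misalignment fraction is a free knob, not an empirical value.
- The numpy network trains tiny models at desk scale; it is a faithful but
  slow stand-alone implementation, not a GPU training stack.
- Rician noise is simulated but the losses assume (approximately) zero-mean
  noise; no Rician bias correction is applied.
- Weighted/robust tensor fits (WLS, RESTORE), higher-order diffusion
  models, and perceptual metrics are out of scope.
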