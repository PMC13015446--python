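# noise2average

Iterative self-supervised denoising of multi-repetition volumetric MRI,
with a diffusion-tensor toolbox, synthetic phantom generators, and masked
image-quality metrics.

## The problem

High-resolution MRI is noisy, and clean reference images for supervised
denoising rarely exist.  What often *does* exist is a small number of
repetitions of the same acquisition — volumes of the same anatomy that
ideally differ only in their noise realization.  Classic noise-to-noise
training (map one repetition to another) degrades badly when the
repetitions also differ in geometry or contrast, which is the practical
reality after imperfect co-registration.

This package implements an iterative residual-learning alternative.  With
`n` co-registered noisy repetitions `y_1 … y_n` of an unknown image `x`:

1. **Iteration 1** — train a CNN `f` to map each repetition to its residual
   against the repetition average: target `r_k = mean(y) − y_k`.  Each
   denoised image `d_k = y_k + f(y_k)` matches the quality of the n-average
   but carries a different noise realization, so their average approaches
   the quality of an `n × n`-repetition average.
2. **Iteration i ≥ 2** — repeat, using the previous iteration's denoised
   average as the training target.  In the ideal case the iteration-`i`
   output is equivalent to the average of `n^(i+1)` raw images.

Two iterations are recommended for a pair of repetitions, one iteration
when more than two are available.  When no ground truth exists, the
unsupervised MSE (`uMSE`) — computed from one extra noisy repetition with a
pair-based noise-variance correction — ranks iterations the same way the
true MSE does and serves as a stopping criterion.

The denoiser is a 3D "modified U-Net": a cascade of 3×3×3 same-padded
convolutions at full resolution (no pooling or up-sampling) with
matched-depth concatenation skips and a linear residual head, trained with
Adam (batch size 1) on brain-masked blocks with a Monte Carlo 80/20
train/validation split re-drawn each epoch.  Whole volumes are covered by
the minimal set of (possibly overlapping) blocks; denoised blocks are
reassembled with overlap averaging.  Training pairs are standardized per
channel to the masked mean/std.

The diffusion toolbox synthesizes DWIs from per-voxel tensors
(`S = S0·exp(−b·gᵀDg)`), fits tensors by log-linear ordinary least squares,
computes FA/MD/AD/RD/V1 maps, and designs diffusion-encoding schemes: six
unit directions minimizing the condition number κ of the 6×6 tensor
transformation matrix (optimum κ ≈ 1.3228), nearest-direction subset
selection under κ < 1.6, and 12-direction set selection by minimal
antipodally symmetric electrostatic energy.

## Worked example

```python
import noise2average as n2a

# 1. Simulate a subject: a 64^3 structural phantom and two noisy repetitions
phantom = n2a.make_structural_phantom((64, 64, 64), seed=7)
sim = n2a.SimulationConfig(sigma=0.3, n_repetitions=2, seed=11)
reps = n2a.simulate_repetitions(phantom, sim)

# 2. Pretrain a small denoiser on a synthetic corpus (transfer learning)
corpus = [n2a.make_structural_phantom((48, 48, 48), seed=100 + i) for i in range(4)]
corpus_sim = n2a.SimulationConfig(sigma=0.5, n_repetitions=2, seed=200)
ncfg = n2a.NetworkConfig(depth=4, channels=8)
tcfg = n2a.TrainingConfig(loss="mse", epochs=10, seed=9, lr_phases=[(1e-3, 10), (1e-4, 5)])
pretrained = n2a.pretrain_on_corpus(corpus, corpus_sim, ncfg, tcfg,
                                    block_shape=(24, 24, 24), seed=9)

# 3. Fine-tune and denoise with the iterative scheme (2 iterations for a pair)
est = n2a.Noise2AverageDenoiser(model=pretrained, epochs_per_iteration=10,
                                learning_rate=1e-4, block_shape=(32, 32, 32), seed=5)
est.fit(reps)

# 4. Evaluate against the noise-free truth
params = n2a.compute_standardization(phantom.truth, phantom.mask)
for label, vol in [("single repetition", reps.repetitions[0]),
                   ("2-repetition average", reps.mean_volume()),
                   ("iteration 1", est.states_[0].output),
                   ("iteration 2", est.states_[1].output)]:
    r = n2a.image_similarity(vol, phantom.truth, phantom.mask, params)
    print(f"{label:22s}  MAE {r.mae:.4f}  PSNR {r.psnr:.2f} dB  SSIM {r.ssim:.4f}")
```

Output (a few minutes on one CPU):

```
single repetition       MAE 0.0400  PSNR 26.00 dB  SSIM 0.7886
2-repetition average    MAE 0.0282  PSNR 29.03 dB  SSIM 0.8640
iteration 1             MAE 0.0204  PSNR 31.54 dB  SSIM 0.9172
iteration 2             MAE 0.0176  PSNR 32.23 dB  SSIM 0.9336
```

Averaging the pair gains ~3 dB over a single repetition, as the noise
arithmetic predicts; the first denoising iteration gains a further ~2.5 dB
over plain averaging, and the second iteration improves all three metrics
again — the pattern the method is designed to deliver.  Metrics use the
standardize-then-`(v+3)/6` transform, so intensities lie roughly in [0, 1]
(PSNR peak 1; SSIM with a 3D Gaussian window, sigma 1.5).

The same workflow runs from the shell on NIfTI inputs:

```bash
n2a pretrain --phantoms 4 --depth 4 --channels 8 --out model.npz
n2a denoise --reps rep1.nii.gz --reps rep2.nii.gz --mask mask.nii.gz \
    --pretrained model.npz --iterations 2 --epochs 10 --out outdir/
n2a evaluate --est outdir/denoised_iter2.nii.gz --truth truth.nii.gz --mask mask.nii.gz
```

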