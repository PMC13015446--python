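"""Masked image-quality metrics and DTI error reports.

Before comparison, intensities are standardized against the brain mask and
mapped by ``v' = ((v - mu)/s + 3)/6`` so that values lie approximately in
[0, 1]; MAE/PSNR/SSIM are then computed over masked voxels with peak /
dynamic range fixed at 1.

The unsupervised MSE (uMSE) estimates the mean squared error of a denoised
image against the unknown truth using one additional noisy repetition and a
pair-based noise-variance correction:

    uMSE = mean_mask((d - y*)^2) - sigma_hat^2,
    sigma_hat^2 = mean_mask((y1 - y2)^2) / 2,

which is unbiased under independent zero-mean noise and makes uMSE usable as
an iteration stopping criterion when no ground truth exists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .dti import DTIMetrics
from .volumes import BrainMask, StandardizationParams, Volume, standardize

__all__ = [
    "MetricsReport",
    "DTIErrorReport",
    "metric_normalize",
    "image_similarity",
    "umse",
    "v1_angular_error",
    "dti_error_report",
]

PSNR_INFINITE = float("inf")


@dataclass
class MetricsReport:
    """Masked image-similarity summary (per-channel and overall means)."""

    mae: float
    psnr: float  # dB; +inf sentinel for identical images
    ssim: float
    umse: float | None = None
    per_channel: dict | None = None

    def as_dict(self) -> dict:
        d = {"mae": self.mae, "psnr": self.psnr, "ssim": self.ssim}
        if self.umse is not None:
            d["umse"] = self.umse
        if self.per_channel is not None:
            d["per_channel"] = self.per_channel
        return d


@dataclass
class DTIErrorReport:
    """Masked MAEs of DTI metrics; V1 in degrees, diffusivities in um^2/ms."""

    v1_error: float
    fa_error: float
    md_error: float
    ad_error: float
    rd_error: float

    def as_dict(self) -> dict:
        return {
            "v1_error_deg": self.v1_error,
            "fa_error": self.fa_error,
            "md_error": self.md_error,
            "ad_error": self.ad_error,
            "rd_error": self.rd_error,
        }


def reports_to_csv(rows: list[dict], path) -> None:
    """Write metric reports (one dict per volume/channel/iteration) as CSV."""
    import pandas as pd

    pd.DataFrame(rows).to_csv(str(path), index=False)


def metric_normalize(volume: Volume, params: StandardizationParams) -> Volume:
    """Standardize then map by (v + 3)/6, placing the masked mean at 0.5."""
    std = standardize(volume, params)
    return std.like((std.channels_view() + 3.0) / 6.0)


def _ssim_map(a: np.ndarray, b: np.ndarray, sigma: float = 1.5,
              truncate: float = 3.5, c1: float = 0.01 ** 2, c2: float = 0.03 ** 2) -> np.ndarray:
    """Local SSIM map with a 3D Gaussian window (11^3 support at sigma=1.5)."""
    filt = lambda x: gaussian_filter(x, sigma=sigma, truncate=truncate, mode="nearest")
    mu_a, mu_b = filt(a), filt(b)
    var_a = filt(a * a) - mu_a ** 2
    var_b = filt(b * b) - mu_b ** 2
    cov = filt(a * b) - mu_a * mu_b
    num = (2 * mu_a * mu_b + c1) * (2 * cov + c2)
    den = (mu_a ** 2 + mu_b ** 2 + c1) * (var_a + var_b + c2)
    return num / den


def image_similarity(
    a: Volume,
    b: Volume,
    mask: BrainMask,
    params: StandardizationParams,
) -> MetricsReport:
    """Masked MAE / PSNR / SSIM between two volumes.

    Both volumes are normalized with the same shared parameters.  PSNR uses
    peak 1 (``10 log10(1/MSE)``) and is reported as +inf when the masked
    voxels are identical.  SSIM is the mean over masked voxels of the local
    3D SSIM map (Gaussian window sigma 1.5, 11^3 support, C1=0.01^2,
    C2=0.03^2 for dynamic range 1).
    """
    if a.spatial_shape != b.spatial_shape or a.n_channels != b.n_channels:
        raise ValueError("volume shapes/channels do not match")
    if mask.spatial_shape != a.spatial_shape:
        raise ValueError("mask shape mismatch")
    an = metric_normalize(a, params).channels_view()
    bn = metric_normalize(b, params).channels_view()
    sel = mask.data
    per_channel: dict[int, dict] = {}
    maes, mses, ssims = [], [], []
    for c in range(an.shape[3]):
        diff = an[..., c][sel] - bn[..., c][sel]
        mae = float(np.mean(np.abs(diff)))
        mse = float(np.mean(diff ** 2))
        ssim = float(np.mean(_ssim_map(an[..., c], bn[..., c])[sel]))
        psnr = PSNR_INFINITE if mse == 0 else float(10.0 * np.log10(1.0 / mse))
        per_channel[c] = {"mae": mae, "psnr": psnr, "ssim": ssim}
        maes.append(mae)
        mses.append(mse)
        ssims.append(ssim)
    mse_all = float(np.mean(mses))
    return MetricsReport(
        mae=float(np.mean(maes)),
        psnr=PSNR_INFINITE if mse_all == 0 else float(10.0 * np.log10(1.0 / mse_all)),
        ssim=float(np.mean(ssims)),
        per_channel=per_channel,
    )


def umse(
    denoised: Volume,
    extra_rep: Volume,
    noise_pair: tuple[Volume, Volume],
    mask: BrainMask,
) -> float:
    """Unsupervised MSE of ``denoised`` against the unknown truth.

    ``extra_rep`` must be a noisy repetition *not* used to produce
    ``denoised``; ``noise_pair`` are two same-noise-level repetitions used to
    estimate the noise variance.
    """
    sel = mask.data
    if not sel.any():
        raise ValueError("empty mask")
    d = denoised.channels_view()[sel]
    y = extra_rep.channels_view()[sel]
    y1 = noise_pair[0].channels_view()[sel]
    y2 = noise_pair[1].channels_view()[sel]
    sigma2 = float(np.mean((y1 - y2) ** 2)) / 2.0
    return float(np.mean((d - y) ** 2)) - sigma2


def v1_angular_error(
    v_est: np.ndarray,
    v_true: np.ndarray,
    tissue_mask: BrainMask,
    renorm_tol: float = 1e-3,
) -> float:
    """Masked mean angle (degrees, antipodally invariant, in [0, 90]) between
    estimated and true principal eigenvector fields."""
    v_est = np.asarray(v_est, dtype=float)
    v_true = np.asarray(v_true, dtype=float)
    sel = tissue_mask.data
    e = v_est[sel]
    t = v_true[sel]
    for name, v in (("v_est", e), ("v_true", t)):
        norms = np.linalg.norm(v, axis=1)
        if np.any(np.abs(norms - 1.0) > renorm_tol):
            import warnings

            warnings.warn(f"{name} contains non-unit vectors; renormalizing")
        v /= np.maximum(norms, 1e-30)[:, None]
    cosang = np.clip(np.abs(np.sum(e * t, axis=1)), 0.0, 1.0)
    return float(np.degrees(np.arccos(cosang)).mean())


def dti_error_report(
    est: DTIMetrics, truth: DTIMetrics, tissue_mask: BrainMask
) -> DTIErrorReport:
    """Masked MAE of FA/MD/AD/RD plus the V1 angular error in degrees."""
    sel = tissue_mask.data
    if est.fa.shape != truth.fa.shape:
        raise ValueError("metric field shapes do not match")
    mae = lambda x, y: float(np.mean(np.abs(x[sel] - y[sel])))
    return DTIErrorReport(
        v1_error=v1_angular_error(est.v1, truth.v1, tissue_mask),
        fa_error=mae(est.fa, truth.fa),
        md_error=mae(est.md, truth.md),
        ad_error=mae(est.ad, truth.ad),
        rd_error=mae(est.rd, truth.rd),
    )
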