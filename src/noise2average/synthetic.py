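"""Synthetic phantoms and multi-repetition noisy data.

The generator emulates the statistical structure the denoising method
assumes: ``n`` co-registered repetitions of the same anatomy that differ by
(i) a small residual affine misalignment left over from imperfect
co-registration and (ii) independent additive noise whose absolute scale is
``sigma`` times the population standard deviation of brain-voxel intensities
of the noise-free truth.  Structural phantoms are nested ellipsoidal
compartments with smooth low-frequency texture; diffusion phantoms carry a
per-voxel tensor field (isotropic, coherent anisotropic, and curved/fanning
compartments) from which DWIs can be synthesized.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.ndimage import affine_transform, gaussian_filter

from .dti import TensorField
from .volumes import BrainMask, RepetitionSet, Volume, save_volume, save_mask

__all__ = [
    "SimulationConfig",
    "Phantom",
    "make_structural_phantom",
    "make_tensor_phantom",
    "simulate_repetitions",
    "write_phantom",
]


@dataclass
class SimulationConfig:
    """Conditions for simulating noisy repetitions.

    ``sigma`` is relative: the absolute noise scale is sigma times the
    population std of truth intensities inside the mask (per channel).  The
    misalignment ranges mirror the transformations used to create imperfectly
    aligned repetitions (translations up to 10 voxels, rotations within +/-3
    degrees per axis, left-right scaling 1.0-1.4); ``misalign_fraction``
    scales the draws down to the small residual level that survives
    co-registration (default 0.1 of the full ranges).
    """

    sigma: float = 0.3
    n_repetitions: int = 2
    noise_model: str = "gaussian"  # or "rician"
    translation_max: float = 10.0  # voxels
    rotation_max: float = 3.0  # degrees per axis
    lr_scale_range: tuple[float, float] = (1.0, 1.4)
    misalign: bool = False
    misalign_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.sigma) < 0):
            raise ValueError("sigma must be nonnegative")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError("noise_model must be 'gaussian' or 'rician'")
        if self.lr_scale_range[0] > self.lr_scale_range[1]:
            raise ValueError("lr_scale_range low > high")

    def to_json(self) -> str:
        d = dict(self.__dict__)
        d["lr_scale_range"] = list(self.lr_scale_range)
        d["sigma"] = np.asarray(self.sigma).tolist()
        return json.dumps(d)


@dataclass
class Phantom:
    """Noise-free ground truth, its brain mask, and (optionally) tensors."""

    truth: Volume
    mask: BrainMask
    tensors: TensorField | None = None


def _ellipsoid(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r = sum(((g - c) / rr) ** 2 for g, c, rr in zip(grids, center, radii))
    return r <= 1.0


def make_structural_phantom(spatial_shape=(64, 64, 64), seed: int = 0) -> Phantom:
    """A structured T1w-like phantom: nested compartments + smooth texture.

    Deterministic under ``seed``.  Contains an outer "brain" ellipsoid
    (mean ~100), a deep "nuclei" shell (~160), and an inner "ventricle"
    (~40), overlaid with low-frequency Gaussian-filtered texture; all
    intensities nonnegative, background zero.  The mask is the outer region.
    """
    shape = tuple(int(s) for s in spatial_shape)
    if any(s < 32 for s in shape):
        raise ValueError("phantom needs at least 32 voxels per axis")
    rng = np.random.default_rng(seed)
    center = tuple(s / 2 + rng.uniform(-1.5, 1.5) for s in shape)
    outer = _ellipsoid(shape, center, tuple(0.42 * s for s in shape))
    middle = _ellipsoid(shape, center, tuple(0.26 * s for s in shape))
    inner = _ellipsoid(
        shape,
        tuple(c + rng.uniform(-2, 2) for c in center),
        tuple(0.11 * s for s in shape),
    )
    truth = np.zeros(shape, dtype=float)
    truth[outer] = 100.0
    truth[middle] = 160.0
    truth[inner] = 40.0
    # smooth low-frequency texture, ~10% of dynamic range
    texture = gaussian_filter(rng.standard_normal(shape), sigma=min(shape) / 8.0)
    texture *= 15.0 / max(texture.std(), 1e-12)
    truth[outer] += texture[outer]
    np.maximum(truth, 0.0, out=truth)
    return Phantom(Volume(truth), BrainMask(outer))


def _rotation_from_axes(dirs: np.ndarray) -> np.ndarray:
    """Orthonormal frame whose first column is the given unit vector."""
    e1 = dirs / np.linalg.norm(dirs)
    helper = np.array([0.0, 0.0, 1.0]) if abs(e1[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e2 = np.cross(e1, helper)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    return np.stack([e1, e2, e3], axis=1)


def make_tensor_phantom(spatial_shape=(48, 48, 48), seed: int = 0) -> Phantom:
    """A diffusion phantom with isotropic, coherent, and fanning compartments.

    All tensors are positive-definite: an isotropic region (0.8 um^2/ms), an
    anisotropic bundle along x and one along y (eigenvalues 1.7/0.3/0.3
    um^2/ms), and a curved/fanning bundle whose principal direction rotates
    tangentially around the volume center.  S0 = 100 inside the mask.
    """
    shape = tuple(int(s) for s in spatial_shape)
    if any(s < 32 for s in shape):
        raise ValueError("phantom needs at least 32 voxels per axis")
    rng = np.random.default_rng(seed)
    center = tuple(s / 2 for s in shape)
    outer = _ellipsoid(shape, center, tuple(0.44 * s for s in shape))

    iso_d = 0.8
    lam = np.array([1.7, 0.3, 0.3])
    comps = np.zeros(shape + (6,), dtype=float)
    comps[..., 0] = comps[..., 1] = comps[..., 2] = iso_d  # isotropic default

    x, y, z = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    # coherent bundle along x: a slab in the lower third
    slab_x = outer & (y < shape[1] * 0.35)
    # coherent bundle along y: a slab in the upper third
    slab_y = outer & (y > shape[1] * 0.65)
    # fanning/curved bundle: tangential directions around the center axis
    rad = np.sqrt((x - center[0]) ** 2 + (z - center[2]) ** 2)
    ring = outer & (rad > 0.15 * shape[0]) & (rad < 0.3 * shape[0]) & ~slab_x & ~slab_y

    def _set_tensor(sel_mask: np.ndarray, dirs: np.ndarray) -> None:
        # dirs: (n_sel, 3) principal directions
        n = int(sel_mask.sum())
        t = np.empty((n, 6))
        for k in range(n):
            r = _rotation_from_axes(dirs[k])
            d = r @ np.diag(lam) @ r.T
            t[k] = [d[0, 0], d[1, 1], d[2, 2], d[0, 1], d[0, 2], d[1, 2]]
        comps[sel_mask] = t

    _set_tensor(slab_x, np.tile([1.0, 0.0, 0.0], (int(slab_x.sum()), 1)))
    _set_tensor(slab_y, np.tile([0.0, 1.0, 0.0], (int(slab_y.sum()), 1)))
    tang = np.stack([-(z[ring] - center[2]), np.zeros(int(ring.sum())), x[ring] - center[0]], axis=1)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    _set_tensor(ring, tang)

    comps[~outer] = 0.0
    comps[~outer, 0] = comps[~outer, 1] = comps[~outer, 2] = 1e-6
    s0 = np.where(outer, 100.0, 0.0)
    field = TensorField(comps, s0)
    truth = Volume(np.where(outer, 100.0, 0.0))
    del rng  # reserved for future randomized geometry
    return Phantom(truth, BrainMask(outer), tensors=field)


def _random_residual_affine(cfg: SimulationConfig, rng: np.random.Generator):
    """A small random affine (matrix, offset) in voxel coordinates."""
    f = cfg.misalign_fraction
    t = rng.uniform(-cfg.translation_max, cfg.translation_max, size=3) * f
    ang = np.radians(rng.uniform(-cfg.rotation_max, cfg.rotation_max, size=3) * f)
    lo, hi = cfg.lr_scale_range
    scale_lr = 1.0 + (rng.uniform(lo, hi) - 1.0) * f

    def rot(axis, a):
        c, s = np.cos(a), np.sin(a)
        m = np.eye(3)
        i, j = [(1, 2), (0, 2), (0, 1)][axis]
        m[i, i] = c
        m[j, j] = c
        m[i, j] = -s
        m[j, i] = s
        return m

    r = rot(0, ang[0]) @ rot(1, ang[1]) @ rot(2, ang[2])
    s = np.diag([scale_lr, 1.0, 1.0])  # left-right = first voxel axis
    return r @ s, t


def simulate_repetitions(phantom: Phantom, config: SimulationConfig) -> RepetitionSet:
    """Simulate ``n`` noisy repetitions of a phantom.

    Per repetition, an optional small residual affine perturbation is applied
    with trilinear resampling (out-of-field voxels become 0 and are removed
    from the shared mask), then noise is added at absolute scale
    ``sigma * std(truth | mask)`` per channel.  Gaussian noise is additive;
    Rician noise is the magnitude of (truth + complex Gaussian) with
    per-component std equal to the same absolute scale.  Deterministic under
    ``config.seed``; noise is independent across repetitions.
    """
    rng = np.random.default_rng(config.seed)
    truth4 = phantom.truth.channels_view().astype(float)
    nchan = truth4.shape[3]
    sigma = np.broadcast_to(np.atleast_1d(np.asarray(config.sigma, float)), (nchan,))
    masked = truth4[phantom.mask.data]
    sigma_abs = sigma * masked.std(axis=0)  # population std of truth in mask

    reps: list[Volume] = []
    mask = phantom.mask.data.copy()
    for _ in range(config.n_repetitions):
        img = truth4
        if config.misalign:
            matrix, offset = _random_residual_affine(config, rng)
            shape3 = truth4.shape[:3]
            center = (np.asarray(shape3) - 1) / 2.0
            # resample about the volume center: x_in = M @ (x_out - c) + c + t
            off = center - matrix @ center + offset
            img = np.stack(
                [
                    affine_transform(truth4[..., c], matrix, offset=off, order=1, cval=0.0)
                    for c in range(nchan)
                ],
                axis=-1,
            )
            support = affine_transform(
                np.ones(shape3), matrix, offset=off, order=1, cval=0.0
            )
            mask &= support > 0.999
        if config.noise_model == "gaussian":
            noisy = img + rng.standard_normal(img.shape) * sigma_abs
        else:  # rician: magnitude of complex Gaussian around the signal
            n_re = rng.standard_normal(img.shape) * sigma_abs
            n_im = rng.standard_normal(img.shape) * sigma_abs
            noisy = np.sqrt((img + n_re) ** 2 + n_im ** 2)
        reps.append(phantom.truth.like(noisy))
    return RepetitionSet(reps, BrainMask(mask))


def write_phantom(phantom: Phantom, outdir, config: SimulationConfig | None = None) -> None:
    """Write truth/mask (and tensors) as NIfTI plus a JSON sidecar."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    save_volume(phantom.truth, out / "truth.nii.gz")
    save_mask(phantom.mask, out / "mask.nii.gz")
    if phantom.tensors is not None:
        save_volume(Volume(phantom.tensors.components), out / "tensors.nii.gz")
        save_volume(Volume(phantom.tensors.s0), out / "s0.nii.gz")
    if config is not None:
        (out / "config.json").write_text(config.to_json())
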