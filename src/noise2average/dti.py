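"""Diffusion tensor toolbox: DWI synthesis, OLS fitting, DTI metrics, and
diffusion-encoding scheme design.

Under the diffusion tensor model the signal along unit direction ``g`` at
b-value ``b`` (s/mm^2) is ``S = S0 * exp(-b * g^T D g)``.  Tensors are stored
as six unique components ``[Dxx, Dyy, Dzz, Dxy, Dxz, Dyz]`` in um^2/ms
(1 um^2/ms = 1e-3 mm^2/s; the unit conversion is handled internally).

Scheme design follows the condition-number approach: six unit directions are
chosen to minimize the 2-norm condition number of the 6x6 matrix mapping
tensor components to signal attenuation exponents, and larger direction sets
are assessed by the antipodally symmetric electrostatic (Coulomb) energy,
which is minimized by uniformly distributed schemes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .volumes import BrainMask, Volume

__all__ = [
    "DirectionSet",
    "TensorField",
    "DTIMetrics",
    "SchemeQuality",
    "encoding_matrix",
    "condition_number",
    "synthesize_dwi",
    "fit_tensor_ols",
    "tensor_metrics",
    "optimize_directions",
    "electrostatic_energy",
    "select_nearest_subsets",
    "pick_min_energy_pair",
    "load_bvecs_bvals",
    "save_bvecs_bvals",
]

# 1 um^2/ms expressed in mm^2/s
UM2_PER_MS_TO_MM2_PER_S = 1e-3


@dataclass
class DirectionSet:
    """Diffusion-encoding directions and b-values, FSL bvec/bval style."""

    directions: np.ndarray  # (N, 3) unit vectors; arbitrary for b=0 entries
    bvalues: np.ndarray  # (N,) in s/mm^2, 0 allowed

    def __post_init__(self) -> None:
        self.directions = np.atleast_2d(np.asarray(self.directions, dtype=float))
        self.bvalues = np.atleast_1d(np.asarray(self.bvalues, dtype=float))
        if self.directions.shape != (self.bvalues.size, 3):
            raise ValueError("directions and bvalues lengths do not match")
        nz = self.bvalues != 0
        norms = np.linalg.norm(self.directions[nz], axis=1)
        if nz.any() and not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("nonzero-b directions must be unit vectors (|g| = 1 within 1e-8)")

    def __len__(self) -> int:
        return self.bvalues.size


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensor (um^2/ms) and S0 (signal units)."""

    components: np.ndarray  # (x, y, z, 6): Dxx, Dyy, Dzz, Dxy, Dxz, Dyz
    s0: np.ndarray  # (x, y, z)

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        self.s0 = np.asarray(self.s0, dtype=float)
        if self.components.ndim != 4 or self.components.shape[3] != 6:
            raise ValueError("components must be (x, y, z, 6)")
        if self.s0.shape != self.components.shape[:3]:
            raise ValueError("s0 shape does not match components")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return tuple(self.components.shape[:3])

    def as_matrices(self) -> np.ndarray:
        """Full symmetric 3x3 tensors, shape (x, y, z, 3, 3)."""
        c = self.components
        m = np.empty(c.shape[:3] + (3, 3), dtype=float)
        m[..., 0, 0] = c[..., 0]
        m[..., 1, 1] = c[..., 1]
        m[..., 2, 2] = c[..., 2]
        m[..., 0, 1] = m[..., 1, 0] = c[..., 3]
        m[..., 0, 2] = m[..., 2, 0] = c[..., 4]
        m[..., 1, 2] = m[..., 2, 1] = c[..., 5]
        return m


@dataclass
class DTIMetrics:
    """Per-voxel eigenvalues (descending), principal eigenvector, and
    the scalar DTI maps FA, MD, AD, RD (diffusivities in um^2/ms)."""

    eigenvalues: np.ndarray  # (x, y, z, 3), lambda1 >= lambda2 >= lambda3
    v1: np.ndarray  # (x, y, z, 3) unit vectors, sign-ambiguous
    fa: np.ndarray
    md: np.ndarray
    ad: np.ndarray
    rd: np.ndarray


@dataclass
class SchemeQuality:
    condition_number: float
    electrostatic_energy: float


def _attenuation_rows(directions: np.ndarray) -> np.ndarray:
    """Rows [gx^2, gy^2, gz^2, 2 gx gy, 2 gx gz, 2 gy gz] for each direction."""
    g = np.atleast_2d(directions)
    return np.stack(
        [
            g[:, 0] ** 2,
            g[:, 1] ** 2,
            g[:, 2] ** 2,
            2 * g[:, 0] * g[:, 1],
            2 * g[:, 0] * g[:, 2],
            2 * g[:, 1] * g[:, 2],
        ],
        axis=1,
    )


def encoding_matrix(directions: np.ndarray) -> np.ndarray:
    """The 6x6 tensor transformation matrix of a six-direction scheme."""
    g = np.atleast_2d(directions)
    if g.shape != (6, 3):
        raise ValueError("encoding_matrix expects exactly six directions")
    return _attenuation_rows(g)


def condition_number(directions: np.ndarray) -> float:
    """2-norm condition number of the six-direction encoding matrix.

    Returns ``inf`` for degenerate geometry (rank-deficient matrix), e.g.
    coplanar or duplicated directions.
    """
    m = encoding_matrix(directions)
    s = np.linalg.svd(m, compute_uv=False)
    if s[-1] <= 1e-12 * s[0]:
        return float("inf")
    return float(s[0] / s[-1])


def synthesize_dwi(field: TensorField, scheme: DirectionSet) -> Volume:
    """Noise-free DWI volumes from a tensor field, one channel per scheme entry.

    b = 0 entries give S0 exactly; otherwise S = S0 exp(-b g^T D g) with b in
    s/mm^2 and D converted from um^2/ms to mm^2/s.
    """
    rows = _attenuation_rows(scheme.directions)  # (N, 6)
    # exponent: -b * (g^T D g) with D in mm^2/s
    quad = field.components @ rows.T * UM2_PER_MS_TO_MM2_PER_S  # (x,y,z,N)
    signals = field.s0[..., None] * np.exp(-scheme.bvalues * quad)
    signals = np.where(scheme.bvalues == 0, field.s0[..., None], signals)
    names = [
        "b0" if b == 0 else f"dwi_{i:02d}" for i, b in enumerate(scheme.bvalues)
    ]
    return Volume(signals, channel_names=names)


def _design_matrix(scheme: DirectionSet) -> np.ndarray:
    """Log-linear design: ln S = [1, -b*rows] @ [ln S0, D]."""
    rows = _attenuation_rows(scheme.directions)
    b = scheme.bvalues[:, None] * UM2_PER_MS_TO_MM2_PER_S
    return np.hstack([np.ones((len(scheme), 1)), -b * rows])


def fit_tensor_ols(
    dwis: Volume,
    scheme: DirectionSet,
    mask: BrainMask | None = None,
    signal_floor: float = 1e-6,
) -> TensorField:
    """Ordinary least squares tensor fit on log-signals.

    Per masked voxel, solves ``ln S = ln S0 - b g^T D g`` with the 7-column
    design ``[1, -b gx^2, -b gy^2, -b gz^2, -2b gx gy, -2b gx gz, -2b gy gz]``.
    Nonpositive signals are clamped to ``signal_floor`` times the median b=0
    (or overall) signal before taking the log.  Voxels outside the mask are
    returned as zero tensors with zero S0.
    """
    data = dwis.channels_view()
    if data.shape[3] != len(scheme):
        raise ValueError("channel count does not match scheme length")
    design = _design_matrix(scheme)
    rank = np.linalg.matrix_rank(design)
    if rank < 7:
        raise ValueError(
            "rank-deficient design: need >= 6 non-collinear nonzero-b directions "
            f"plus a b=0 (or full-rank) scheme; rank={rank}"
        )
    if mask is None:
        sel = np.ones(data.shape[:3], dtype=bool)
    else:
        if mask.spatial_shape != dwis.spatial_shape:
            raise ValueError("mask shape mismatch")
        sel = mask.data
    signals = data[sel]  # (n_vox, N)
    b0 = scheme.bvalues == 0
    scale = np.median(signals[:, b0]) if b0.any() else np.median(signals)
    scale = scale if scale > 0 else 1.0
    floor = signal_floor * scale
    logs = np.log(np.maximum(signals, floor))
    coef, *_ = np.linalg.lstsq(design, logs.T, rcond=None)  # (7, n_vox)
    comps = np.zeros(data.shape[:3] + (6,), dtype=float)
    s0 = np.zeros(data.shape[:3], dtype=float)
    comps[sel] = coef[1:].T
    s0[sel] = np.exp(coef[0])
    return TensorField(comps, s0)


def tensor_metrics(field: TensorField) -> DTIMetrics:
    """Eigendecomposition-based DTI maps.

    FA = sqrt(3/2) * ||lambda - MD|| / ||lambda||; AD = lambda1;
    RD = (lambda2 + lambda3)/2; MD = mean(lambda).  V1 is the unit
    eigenvector of lambda1 with unconstrained sign.
    """
    m = field.as_matrices()
    if not np.all(np.isfinite(m)):
        raise ValueError("non-finite tensor components")
    w, v = np.linalg.eigh(m)  # ascending
    w = w[..., ::-1]  # descending
    v1 = v[..., :, 2]  # eigenvector of the largest eigenvalue
    md = w.mean(axis=-1)
    num = np.linalg.norm(w - md[..., None], axis=-1)
    den = np.linalg.norm(w, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    fa = np.where(den > 0, fa, 0.0)
    return DTIMetrics(
        eigenvalues=w,
        v1=v1,
        fa=fa,
        md=md,
        ad=w[..., 0],
        rd=(w[..., 1] + w[..., 2]) / 2.0,
    )


# ---------------------------------------------------------------------------
# Scheme design


def _angles_to_dirs(x: np.ndarray) -> np.ndarray:
    th, ph = x[:6], x[6:]
    st = np.sin(th)
    return np.stack([st * np.cos(ph), st * np.sin(ph), np.cos(th)], axis=1)


def _kappa_of_angles(x: np.ndarray) -> float:
    k = condition_number(_angles_to_dirs(x))
    return k if np.isfinite(k) else 1e9


def optimize_directions(
    n: int = 6,
    restarts: int = 100,
    seed: int | None = None,
    polish_top: int = 10,
    polish_rounds: int = 6,
) -> tuple[DirectionSet, SchemeQuality]:
    """Multi-start minimization of the six-direction condition number.

    Each restart draws six uniformly random unit vectors and runs a
    Nelder-Mead local search on the spherical angles; the best candidates are
    then polished with alternating Powell / Nelder-Mead rounds.  The best
    condition number found is non-increasing in ``restarts``.
    """
    if n != 6:
        raise ValueError("condition-number design is defined for six directions")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    rng = np.random.default_rng(seed)
    candidates: list[tuple[float, np.ndarray]] = []
    for _ in range(restarts):
        x0 = np.concatenate(
            [np.arccos(rng.uniform(-1, 1, 6)), rng.uniform(0, 2 * np.pi, 6)]
        )
        res = minimize(
            _kappa_of_angles, x0, method="Nelder-Mead", options={"maxiter": 2000}
        )
        candidates.append((res.fun, res.x))
    candidates.sort(key=lambda t: t[0])
    best_f, best_x = candidates[0]
    for f, x in candidates[: min(polish_top, len(candidates))]:
        for _ in range(polish_rounds):
            r1 = minimize(
                _kappa_of_angles, x, method="Powell",
                options={"maxiter": 20000, "xtol": 1e-12, "ftol": 1e-14},
            )
            r2 = minimize(
                _kappa_of_angles, r1.x, method="Nelder-Mead",
                options={"maxiter": 10000, "xatol": 1e-12, "fatol": 1e-14},
            )
            x, f = r2.x, r2.fun
        if f < best_f:
            best_f, best_x = f, x
    dirs = _angles_to_dirs(best_x)
    scheme = DirectionSet(dirs, np.full(6, 1000.0))
    quality = SchemeQuality(float(best_f), electrostatic_energy(dirs))
    return scheme, quality


def electrostatic_energy(directions: np.ndarray) -> float:
    """Antipodally symmetric Coulomb energy of a set of unit directions.

    ``E = sum_{i<j} 1/|u_i - u_j| + 1/|u_i + u_j|``; parallel or antiparallel
    pairs give ``inf``.
    """
    u = np.atleast_2d(np.asarray(directions, dtype=float))
    if u.shape[0] < 2:
        raise ValueError("need at least two directions")
    diff = np.linalg.norm(u[:, None, :] - u[None, :, :], axis=-1)
    summ = np.linalg.norm(u[:, None, :] + u[None, :, :], axis=-1)
    iu = np.triu_indices(u.shape[0], k=1)
    d, s = diff[iu], summ[iu]
    if np.any(d < 1e-12) or np.any(s < 1e-12):
        return float("inf")
    return float(np.sum(1.0 / d + 1.0 / s))


def _angular_distance(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Antipodally invariant arc angle between direction sets (radians)."""
    c = np.clip(np.abs(u @ v.T), 0.0, 1.0)
    return np.arccos(c)


def select_nearest_subsets(
    pool: DirectionSet,
    reference: DirectionSet,
    n_rotations: int = 100,
    kappa_max: float = 1.6,
    seed: int | None = None,
    rotations: list[np.ndarray] | None = None,
) -> list[np.ndarray]:
    """Candidate six-direction subsets of a pool, near random rotations of a
    reference scheme.

    For each uniformly random rotation of the reference directions, the
    nearest pool direction (antipodally invariant arc angle) is picked for
    each rotated direction; the subset of indices is kept iff all six picks
    are distinct and the subset's condition number is below ``kappa_max``.

    Explicit 3x3 ``rotations`` may be supplied instead of random sampling.
    Returns a list of index arrays into ``pool.directions``; an empty list
    is a valid outcome.
    """
    pdirs = pool.directions
    rdirs = reference.directions
    if pdirs.shape[0] < 6:
        raise ValueError("pool must contain at least six directions")
    if rdirs.shape[0] != 6:
        raise ValueError("reference must contain exactly six directions")
    rng = np.random.default_rng(seed)
    if rotations is None:
        rotations = [Rotation.random(rng=rng).as_matrix() for _ in range(n_rotations)]
    subsets: list[np.ndarray] = []
    for rot in rotations:
        rotated = rdirs @ rot.T
        idx = np.argmin(_angular_distance(rotated, pdirs), axis=1)
        if len(set(idx.tolist())) != 6:
            continue
        if condition_number(pdirs[idx]) < kappa_max:
            subsets.append(idx)
    return subsets


def pick_min_energy_pair(
    subsets: list[np.ndarray],
    pool: DirectionSet,
    n_trials: int | None = None,
    seed: int | None = None,
) -> tuple[int, int]:
    """Pick the pair of six-direction subsets whose pooled 12 directions have
    the lowest electrostatic energy.

    All pairs are evaluated when ``n_trials`` is ``None`` or at least the
    number of pairs; otherwise ``n_trials`` random pairs are sampled.
    Pairs with infinite energy (coincident directions) are excluded.
    Returns the pair of indices into ``subsets``.
    """
    m = len(subsets)
    if m < 2:
        raise ValueError("need at least two subsets")
    all_pairs = [(i, j) for i in range(m) for j in range(i + 1, m)]
    if n_trials is not None and n_trials < len(all_pairs):
        rng = np.random.default_rng(seed)
        chosen = rng.choice(len(all_pairs), size=n_trials, replace=False)
        pairs = [all_pairs[k] for k in chosen]
    else:
        pairs = all_pairs
    best, best_e = None, float("inf")
    for i, j in pairs:
        dirs = np.vstack([pool.directions[subsets[i]], pool.directions[subsets[j]]])
        e = electrostatic_energy(dirs)
        if e < best_e:
            best, best_e = (i, j), e
    if best is None:
        raise ValueError("no finite-energy pair found")
    return best


# ---------------------------------------------------------------------------
# FSL-style bvec/bval text files


def load_bvecs_bvals(bvec_path, bval_path) -> DirectionSet:
    bvecs = np.loadtxt(str(bvec_path))  # 3 x N
    bvals = np.atleast_1d(np.loadtxt(str(bval_path)))
    if bvecs.ndim == 1:
        bvecs = bvecs[:, None]
    if bvecs.shape[0] != 3:
        raise ValueError("bvec file must be 3 x N")
    return DirectionSet(bvecs.T, bvals)


def save_bvecs_bvals(scheme: DirectionSet, bvec_path, bval_path) -> None:
    np.savetxt(str(bvec_path), scheme.directions.T, fmt="%.10f")
    np.savetxt(str(bval_path), scheme.bvalues[None, :], fmt="%.1f")
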