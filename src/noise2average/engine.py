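"""The iterative self-supervised denoising loop and its baselines.

Given ``n`` co-registered noisy repetitions, each iteration trains the
denoiser to map every repetition to the residual between it and the current
training target — the ``n``-repetition average at iteration 1, and the
previous iteration's denoised average thereafter — then denoises every
repetition and averages the results.  In the ideal case the iteration-``i``
output matches the average of ``n^(i+1)`` raw noisy images, which is the
reason a few iterations recover substantially higher SNR than plain
averaging.

Oracle denoisers (perfect-target, matched-noise, identity) stand in for the
trained network in property tests of that arithmetic.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .blocks import BlockGrid, plan_blocks
from .network import (
    DenoiserModel,
    NetworkConfig,
    TrainingConfig,
    build_munet,
    denoise_volume,
    train_denoiser,
)
from .synthetic import Phantom, SimulationConfig, simulate_repetitions
from .volumes import (
    BrainMask,
    RepetitionSet,
    StandardizationParams,
    Volume,
    compute_standardization,
    standardize,
)

__all__ = [
    "IterationState",
    "RunConfig",
    "OracleDenoiser",
    "build_iteration_target",
    "make_training_pairs",
    "noise2average_run",
    "noise2noise_run",
    "supervised_run",
    "pretrain_on_corpus",
    "clone_model",
    "default_iterations",
]


@dataclass
class IterationState:
    """Record of one iteration: its training target, the per-repetition
    denoised volumes, and their voxelwise average (the iteration's output)."""

    index: int  # 1-based
    target: Volume
    denoised: list[Volume]
    output: Volume


@dataclass
class RunConfig:
    """Settings of a denoising run."""

    iterations: int = 2
    mode: str = "n2a"  # n2a | n2n | supervised
    networks_per: str = "shared"  # shared | per_channel | per_volume
    epochs_per_iteration: int = 10
    warm_start: bool = True
    block_shape: tuple[int, int, int] = (80, 80, 80)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.mode not in ("n2a", "n2n", "supervised"):
            raise ValueError("mode must be n2a, n2n or supervised")
        if self.networks_per not in ("shared", "per_channel", "per_volume"):
            raise ValueError("networks_per must be shared, per_channel or per_volume")


def default_iterations(n_repetitions: int) -> int:
    """Recommended iteration count: two for a noisy pair, one for n > 2."""
    return 2 if n_repetitions == 2 else 1


@dataclass
class OracleDenoiser:
    """Idealized denoisers for property tests.

    ``perfect_target`` returns the current training target exactly (the
    ideal CNN); ``matched_noise`` returns the truth plus fresh independent
    Gaussian noise whose variance matches the current target's noise
    variance; ``identity`` returns its input unchanged.
    """

    kind: str  # perfect_target | matched_noise | identity
    truth: Volume | None = None  # required for matched_noise
    seed: int = 0
    _rng: np.random.Generator = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.kind not in ("perfect_target", "matched_noise", "identity"):
            raise ValueError(f"unknown oracle kind {self.kind!r}")
        if self.kind == "matched_noise" and self.truth is None:
            raise ValueError("matched_noise oracle needs the ground truth")
        self._rng = np.random.default_rng(self.seed)

    def denoise(self, volume: Volume, target: Volume, mask: BrainMask) -> Volume:
        if self.kind == "identity":
            return volume
        if self.kind == "perfect_target":
            return target
        resid = target.channels_view() - self.truth.channels_view()
        var = float(np.mean(resid[mask.data] ** 2))
        noise = self._rng.standard_normal(self.truth.channels_view().shape) * np.sqrt(var)
        return self.truth.like(self.truth.channels_view() + noise)


def build_iteration_target(
    reps: RepetitionSet, i: int, prev_state: IterationState | None = None
) -> Volume:
    """Training target for iteration ``i``: the repetition mean at i = 1, the
    previous iteration's denoised average for i >= 2."""
    if i < 1:
        raise ValueError("iteration index is 1-based")
    if i == 1:
        if reps.n < 2:
            raise ValueError("denoising requires at least 2 repetitions")
        return reps.mean_volume()
    if prev_state is None:
        raise ValueError("iterations >= 2 need the previous IterationState")
    return prev_state.output


def make_training_pairs(
    reps: RepetitionSet,
    target: Volume,
    grid: BlockGrid,
    params: StandardizationParams,
    skip_empty: bool = True,
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Standardized (input block, residual block, mask block) triples for
    every repetition and grid block: residual = target - input."""
    if target.spatial_shape != reps.spatial_shape:
        raise ValueError("target shape does not match repetitions")
    from .blocks import extract_blocks

    target_std = standardize(target, params)
    mask_blocks = _extract_mask_blocks(reps.mask, grid)
    pairs = []
    for rep in reps.repetitions:
        rep_std = standardize(rep, params)
        in_blocks = extract_blocks(rep_std, grid)
        tgt_blocks = extract_blocks(target_std, grid)
        for inp, tgt, msk in zip(in_blocks, tgt_blocks, mask_blocks):
            if skip_empty and not msk.any():
                continue
            pairs.append((inp, tgt - inp, msk))
    return pairs


def _extract_mask_blocks(mask: BrainMask, grid: BlockGrid) -> list[np.ndarray]:
    bx, by, bz = grid.block_shape
    return [
        mask.data[x : x + bx, y : y + by, z : z + bz]
        for (x, y, z) in grid.origins
    ]


def clone_model(model: DenoiserModel) -> DenoiserModel:
    """A fresh model with identical architecture and copied weights."""
    new = build_munet(model.config, seed=model.net.seed)
    new.net.load_state_arrays({k: v.copy() for k, v in model.net.state_arrays().items()})
    new.training_log = list(model.training_log)
    return new


def _single_channel(volume: Volume, c: int) -> Volume:
    return Volume(volume.channels_view()[..., c].copy(), volume.voxel_size)


def _denoise_with_models(
    models,
    networks_per: str,
    volume: Volume,
    mask: BrainMask,
    params: StandardizationParams,
    grid: BlockGrid,
) -> Volume:
    if networks_per == "shared":
        return denoise_volume(models[0], volume, mask, params, grid)
    if networks_per == "per_channel":
        chans = [
            denoise_volume(
                models[c],
                _single_channel(volume, c),
                mask,
                StandardizationParams(params.mean[c : c + 1], params.std[c : c + 1]),
                grid,
            ).channels_view()[..., 0]
            for c in range(volume.n_channels)
        ]
        return volume.like(np.stack(chans, axis=-1))
    # per_volume: every model sees all channels, predicts one channel's residual
    from .blocks import assemble_blocks, extract_blocks

    std = standardize(volume, params)
    in_blocks = extract_blocks(std, grid)
    out_chans = []
    for c in range(volume.n_channels):
        den_blocks = []
        for blk in in_blocks:
            residual = models[c].predict_residual(blk)
            den_blocks.append(blk[..., c : c + 1] + residual.astype(float))
        out_chans.append(assemble_blocks(den_blocks, grid, volume.spatial_shape)[..., 0])
    out = std.like(np.stack(out_chans, axis=-1))
    return standardize(out, params, inverse=True)


def _prepare_models(model, reps: RepetitionSet, cfg: RunConfig) -> list[DenoiserModel]:
    nchan = reps.n_channels
    if isinstance(model, (list, tuple)):
        return list(model)
    if cfg.networks_per == "shared":
        return [model]
    return [clone_model(model) for _ in range(nchan)]


def _pairs_for_mode(
    reps: RepetitionSet,
    target: Volume,
    grid: BlockGrid,
    params: StandardizationParams,
    networks_per: str,
    channel: int | None = None,
):
    if networks_per == "shared":
        return make_training_pairs(reps, target, grid, params)
    if networks_per == "per_channel":
        c = channel
        sub_reps = RepetitionSet([_single_channel(r, c) for r in reps.repetitions], reps.mask)
        sub_params = StandardizationParams(params.mean[c : c + 1], params.std[c : c + 1])
        return make_training_pairs(sub_reps, _single_channel(target, c), grid, sub_params)
    # per_volume: input is all channels, residual target is one channel
    pairs = make_training_pairs(reps, target, grid, params)
    c = channel
    return [(inp, tgt[..., c : c + 1], msk) for inp, tgt, msk in pairs]


def noise2average_run(
    reps: RepetitionSet,
    model,
    cfg: RunConfig,
    tcfg: TrainingConfig | None = None,
) -> list[IterationState]:
    """Run the iterative denoising loop.

    ``model`` may be a trainable :class:`DenoiserModel` (fine-tuned
    ``cfg.epochs_per_iteration`` epochs before denoising at every iteration,
    warm-started across iterations unless ``cfg.warm_start`` is False), a
    list of models (multi-network modes), or an :class:`OracleDenoiser`.
    Returns the list of per-iteration states.
    """
    if reps.n < 2:
        raise ValueError("denoising requires at least 2 repetitions")
    is_oracle = isinstance(model, OracleDenoiser)
    mean_vol = reps.mean_volume()
    states: list[IterationState] = []
    if not is_oracle:
        params = compute_standardization(mean_vol, reps.mask)
        grid = plan_blocks(reps.spatial_shape, cfg.block_shape)
        models = _prepare_models(model, reps, cfg)
        initial_states = [
            {k: v.copy() for k, v in m.net.state_arrays().items()} for m in models
        ]
    prev = None
    for i in range(1, cfg.iterations + 1):
        target = build_iteration_target(reps, i, prev)
        if is_oracle:
            denoised = [model.denoise(r, target, reps.mask) for r in reps.repetitions]
        else:
            if not cfg.warm_start and i > 1:
                for m, st in zip(models, initial_states):
                    m.net.load_state_arrays({k: v.copy() for k, v in st.items()})
            for c, m in enumerate(models):
                channel = None if cfg.networks_per == "shared" else c
                pairs = _pairs_for_mode(reps, target, grid, params, cfg.networks_per, channel)
                train_denoiser(m, pairs, _replace_tcfg(tcfg, cfg, i, c))
            denoised = [
                _denoise_with_models(models, cfg.networks_per, r, reps.mask, params, grid)
                for r in reps.repetitions
            ]
        stack = np.stack([d.channels_view() for d in denoised], axis=0)
        output = denoised[0].like(stack.mean(axis=0))
        prev = IterationState(index=i, target=target, denoised=denoised, output=output)
        states.append(prev)
    return states


def _replace_tcfg(tcfg: TrainingConfig, cfg: RunConfig, i: int, c: int) -> TrainingConfig:
    new = copy.deepcopy(tcfg)
    new.epochs = cfg.epochs_per_iteration
    new.seed = (tcfg.seed + 1000 * i + c) % (2 ** 31)
    return new


def noise2noise_run(
    reps: RepetitionSet,
    model,
    cfg: RunConfig | None = None,
    tcfg: TrainingConfig | None = None,
) -> Volume:
    """Noise-to-noise baseline: each repetition's training target is the next
    repetition (cyclically; the mutual pairing for n = 2).  After training,
    every repetition is denoised and the results averaged."""
    if reps.n < 2:
        raise ValueError("noise2noise requires at least 2 repetitions")
    cfg = cfg or RunConfig(iterations=1, mode="n2n")
    is_oracle = isinstance(model, OracleDenoiser)
    targets = [reps.repetitions[(k + 1) % reps.n] for k in range(reps.n)]
    if is_oracle:
        denoised = [
            model.denoise(r, t, reps.mask) for r, t in zip(reps.repetitions, targets)
        ]
    else:
        params = compute_standardization(reps.mean_volume(), reps.mask)
        grid = plan_blocks(reps.spatial_shape, cfg.block_shape)
        from .blocks import extract_blocks

        mask_blocks = _extract_mask_blocks(reps.mask, grid)
        pairs = []
        for rep, tgt in zip(reps.repetitions, targets):
            rep_std = standardize(rep, params)
            tgt_std = standardize(tgt, params)
            for inp, t, msk in zip(
                extract_blocks(rep_std, grid), extract_blocks(tgt_std, grid), mask_blocks
            ):
                if msk.any():
                    pairs.append((inp, t - inp, msk))
        step_tcfg = _replace_tcfg(tcfg, cfg, 1, 0)
        train_denoiser(model, pairs, step_tcfg)
        denoised = [denoise_volume(model, r, reps.mask, params, grid) for r in reps.repetitions]
    stack = np.stack([d.channels_view() for d in denoised], axis=0)
    return denoised[0].like(stack.mean(axis=0))


def supervised_run(
    reps: RepetitionSet,
    truth: Volume,
    model,
    tcfg: TrainingConfig | None = None,
    cfg: RunConfig | None = None,
) -> Volume:
    """Supervised upper bound: map the repetition average to its residual
    against the ground truth, then denoise the average."""
    if truth.spatial_shape != reps.spatial_shape or truth.n_channels != reps.n_channels:
        raise ValueError("truth shape does not match repetitions")
    cfg = cfg or RunConfig(iterations=1, mode="supervised")
    mean_vol = reps.mean_volume()
    if isinstance(model, OracleDenoiser):
        return model.denoise(mean_vol, truth, reps.mask)
    params = compute_standardization(mean_vol, reps.mask)
    grid = plan_blocks(reps.spatial_shape, cfg.block_shape)
    input_set = RepetitionSet([mean_vol], reps.mask)
    pairs = make_training_pairs(input_set, truth, grid, params)
    if len(pairs) < 2:  # single-block volumes: duplicate so a split exists
        pairs = pairs * 2
    step_tcfg = _replace_tcfg(tcfg, cfg, 1, 0)
    train_denoiser(model, pairs, step_tcfg)
    return denoise_volume(model, mean_vol, reps.mask, params, grid)


def pretrain_on_corpus(
    phantoms: list[Phantom],
    sim: SimulationConfig,
    ncfg: NetworkConfig,
    tcfg: TrainingConfig,
    block_shape: tuple[int, int, int] = (80, 80, 80),
    seed: int = 0,
) -> DenoiserModel:
    """Pretrain a denoiser on a simulated corpus.

    For every phantom (a pretraining "subject"), noisy volumes are simulated
    and supervised residual pairs built against the phantom's own truth.
    Subjects are split 80/20 into train/validation once; training then runs
    the learning-rate phases in ``tcfg`` (default: the two-phase 1e-4 then
    1e-5 schedule).
    """
    if len(phantoms) < 2:
        raise ValueError("pretraining needs at least 2 phantoms")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(phantoms))
    n_val = max(1, round(0.2 * len(phantoms)))
    val_ids = set(order[:n_val].tolist())

    def subject_pairs(ph: Phantom, subject_seed: int):
        local_sim = copy.deepcopy(sim)
        local_sim.seed = subject_seed
        reps = simulate_repetitions(ph, local_sim)
        params = compute_standardization(ph.truth, reps.mask)
        grid = plan_blocks(ph.truth.spatial_shape, block_shape)
        return make_training_pairs(reps, ph.truth, grid, params)

    train_pairs, val_pairs = [], []
    for idx, ph in enumerate(phantoms):
        pairs = subject_pairs(ph, (sim.seed + idx) % (2 ** 31))
        (val_pairs if idx in val_ids else train_pairs).extend(pairs)

    model = build_munet(ncfg, seed=seed)
    if tcfg.lr_phases is None:
        tcfg = copy.deepcopy(tcfg)
        tcfg.lr_phases = [(1e-4, tcfg.epochs), (1e-5, tcfg.epochs)]
    train_denoiser(model, train_pairs, tcfg, val_pairs=val_pairs)
    model.training_log[-1]["n_train_subjects"] = len(phantoms) - n_val
    model.training_log[-1]["n_val_subjects"] = n_val
    return model
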