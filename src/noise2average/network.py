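"""MU-Net denoiser construction, masked-loss training, and whole-volume
blockwise residual inference.

The denoiser maps a standardized noisy block to a residual block of the same
shape; restoration adds the predicted residual back to the input.  Training
uses Adam with batch size 1 on (input, residual-target, mask) block triples,
re-drawing an 80/20 train/validation split every epoch (Monte Carlo
cross-validation), with the loss evaluated only inside the brain mask.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ._nn import Adam, MUNet
from .blocks import BlockGrid, assemble_blocks, extract_blocks
from .volumes import BrainMask, StandardizationParams, Volume, standardize

__all__ = [
    "NetworkConfig",
    "TrainingConfig",
    "DenoiserModel",
    "build_munet",
    "masked_loss",
    "train_denoiser",
    "denoise_volume",
    "TrainingDivergenceError",
]


class TrainingDivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass
class NetworkConfig:
    """MU-Net architecture parameters.

    The kernel is fixed at 3x3x3 with stride 1 (same padding), so the
    theoretical receptive field is ``2*depth + 1`` voxels per axis.  The
    deep T1w variant uses depth 18 / 64 channels; the multi-channel
    diffusion variant uses depth 10 / 192 channels with batch normalization
    before every convolution.
    """

    depth: int = 18
    channels: int = 64
    input_channels: int = 1
    output_channels: int = 1
    use_batchnorm: bool = False
    zero_init_head: bool = True

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if min(self.channels, self.input_channels, self.output_channels) < 1:
            raise ValueError("channel counts must be >= 1")

    @property
    def receptive_field(self) -> int:
        return 2 * self.depth + 1

    @classmethod
    def t1w_variant(cls, input_channels: int = 1) -> "NetworkConfig":
        return cls(depth=18, channels=64, input_channels=input_channels,
                   output_channels=input_channels, use_batchnorm=False)

    @classmethod
    def diffusion_variant(cls, input_channels: int, output_channels: int | None = None) -> "NetworkConfig":
        return cls(depth=10, channels=192, input_channels=input_channels,
                   output_channels=output_channels or input_channels, use_batchnorm=True)


@dataclass
class TrainingConfig:
    """Optimization settings: Adam (default moments), batch size 1,
    Monte Carlo 80/20 split re-drawn at each epoch."""

    loss: str = "mse"  # "mse" for T1w-like data, "mae" for diffusion
    learning_rate: float = 1e-4
    epochs: int = 10
    batch_size: int = 1
    val_fraction: float = 0.2
    seed: int = 0
    lr_phases: list[tuple[float, int]] | None = None  # [(lr, epochs), ...]

    def __post_init__(self) -> None:
        if self.loss not in ("mse", "mae"):
            raise ValueError("loss must be 'mse' or 'mae'")
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must be in (0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class DenoiserModel:
    """A trainable residual denoiser plus its architecture and training log."""

    config: NetworkConfig
    net: MUNet
    training_log: list[dict] = field(default_factory=list)

    @property
    def n_parameters(self) -> int:
        return self.net.n_parameters()

    def predict_residual(self, block: np.ndarray, training: bool = False) -> np.ndarray:
        """block: (X, Y, Z, c) standardized -> residual of the same shape."""
        x = np.moveaxis(np.atleast_3d(block), -1, 0)
        out = self.net.forward(x, training=training)
        return np.moveaxis(out, 0, -1)

    # -- checkpointing -------------------------------------------------------
    def save(self, path) -> None:
        meta = json.dumps({
            "depth": self.config.depth,
            "channels": self.config.channels,
            "input_channels": self.config.input_channels,
            "output_channels": self.config.output_channels,
            "use_batchnorm": self.config.use_batchnorm,
            "zero_init_head": self.config.zero_init_head,
            "seed": self.net.seed,
        })
        np.savez(str(path), _meta=np.array(meta),
                 **self.net.state_arrays())

    @classmethod
    def load(cls, path) -> "DenoiserModel":
        with np.load(str(path), allow_pickle=False) as data:
            meta = json.loads(str(data["_meta"]))
            config = NetworkConfig(
                depth=meta["depth"], channels=meta["channels"],
                input_channels=meta["input_channels"],
                output_channels=meta["output_channels"],
                use_batchnorm=meta["use_batchnorm"],
                zero_init_head=meta.get("zero_init_head", True),
            )
            model = build_munet(config, seed=meta["seed"])
            model.net.load_state_arrays(data)
        return model

    def write_training_log(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.training_log).to_csv(str(path), index=False)


def build_munet(config: NetworkConfig, seed: int = 0) -> DenoiserModel:
    """Construct a MU-Net denoiser with seed-deterministic initialization."""
    net = MUNet(config.depth, config.channels, config.input_channels,
                config.output_channels, config.use_batchnorm, seed=seed,
                zero_init_head=config.zero_init_head)
    return DenoiserModel(config=config, net=net)


def masked_loss(prediction: np.ndarray, target: np.ndarray,
                mask: np.ndarray, loss_type: str = "mse") -> float:
    """Mean |diff| (mae) or diff^2 (mse) over masked voxels and channels."""
    prediction = np.asarray(prediction)
    target = np.asarray(target)
    if prediction.shape != target.shape:
        raise ValueError("prediction/target shape mismatch")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != prediction.shape[:3]:
        raise ValueError("mask shape mismatch")
    if not mask.any():
        return 0.0
    diff = prediction[mask] - target[mask]
    if loss_type == "mse":
        return float(np.mean(diff ** 2))
    if loss_type == "mae":
        return float(np.mean(np.abs(diff)))
    raise ValueError("loss_type must be 'mse' or 'mae'")


def _loss_and_grad(pred: np.ndarray, target: np.ndarray, mask: np.ndarray,
                   loss_type: str) -> tuple[float, np.ndarray]:
    m = mask[..., None] if pred.ndim == 4 else mask
    nm = float(m.sum()) * (pred.shape[-1] if pred.ndim == 4 else 1)
    diff = (pred - target) * m
    if loss_type == "mse":
        loss = float(np.sum(diff ** 2)) / nm
        grad = (2.0 / nm) * diff
    else:
        loss = float(np.sum(np.abs(diff))) / nm
        grad = np.sign(diff) / nm
    return loss, grad.astype(np.float32)


def _split_epoch(n: int, val_fraction: float, rng: np.random.Generator):
    perm = rng.permutation(n)
    n_val = max(1, round(val_fraction * n))
    n_val = min(n_val, n - 1)  # keep at least one training pair
    return perm[n_val:], perm[:n_val]


def _prepare_pairs(pairs):
    return [
        (
            np.ascontiguousarray(np.moveaxis(np.atleast_3d(inp), -1, 0), dtype=np.float32),
            np.asarray(tgt, dtype=np.float32),
            np.asarray(msk, dtype=bool),
        )
        for inp, tgt, msk in pairs
    ]


def train_denoiser(model: DenoiserModel, pairs: list, tcfg: TrainingConfig,
                   val_pairs: list | None = None) -> DenoiserModel:
    """Train a residual denoiser on (input, residual-target, mask) triples.

    Runs Adam updates with batch size 1.  By default the 80/20 split is
    re-drawn from ``pairs`` every epoch (Monte Carlo cross-validation) and
    per-epoch train/validation losses are appended to the model's training
    log; when a fixed ``val_pairs`` list is given (subject-level pretraining
    splits), all of ``pairs`` are trained on and ``val_pairs`` validates.
    Deterministic under ``tcfg.seed`` with single-threaded execution.
    """
    if len(pairs) < 2 and val_pairs is None:
        raise ValueError("need at least 2 training pairs for a split")
    rng = np.random.default_rng(tcfg.seed)
    phases = tcfg.lr_phases or [(tcfg.learning_rate, tcfg.epochs)]
    opt = Adam(model.net.parameters(), lr=phases[0][0])
    epoch_global = len(model.training_log)
    prepared = _prepare_pairs(pairs)
    fixed_val = _prepare_pairs(val_pairs) if val_pairs is not None else None
    for lr, n_epochs in phases:
        opt.lr = lr
        for _ in range(n_epochs):
            if fixed_val is None:
                train_idx, val_idx = _split_epoch(len(prepared), tcfg.val_fraction, rng)
            else:
                train_idx, val_idx = rng.permutation(len(prepared)), None
            train_losses = []
            for i in train_idx:
                x, tgt, msk = prepared[i]
                if not msk.any():
                    continue
                pred = np.moveaxis(model.net.forward(x, training=True), 0, -1)
                if tgt.ndim == 3:
                    pred = pred[..., 0]
                loss, grad = _loss_and_grad(pred, tgt, msk, tcfg.loss)
                if not np.isfinite(loss):
                    raise TrainingDivergenceError(
                        f"non-finite training loss at epoch {epoch_global}"
                    )
                train_losses.append(loss)
                gout = grad if grad.ndim == 4 else grad[..., None]
                model.net.zero_grad()
                model.net.backward(np.moveaxis(gout, -1, 0))
                opt.step()
            val_losses = []
            val_items = fixed_val if fixed_val is not None else [prepared[i] for i in val_idx]
            for x, tgt, msk in val_items:
                if not msk.any():
                    continue
                pred = np.moveaxis(model.net.forward(x, training=False), 0, -1)
                if tgt.ndim == 3:
                    pred = pred[..., 0]
                val_losses.append(masked_loss(
                    np.atleast_3d(pred), np.atleast_3d(tgt), msk, tcfg.loss))
            model.training_log.append({
                "epoch": epoch_global,
                "lr": lr,
                "train_loss": float(np.mean(train_losses)) if train_losses else float("nan"),
                "val_loss": float(np.mean(val_losses)) if val_losses else float("nan"),
            })
            epoch_global += 1
    return model


def denoise_volume(
    model: DenoiserModel,
    volume: Volume,
    mask: BrainMask,
    params: StandardizationParams,
    grid: BlockGrid,
) -> Volume:
    """Blockwise residual denoising of a whole volume.

    standardize -> per-block residual prediction -> denoised block =
    input + residual -> assemble with overlap averaging -> invert
    standardization.
    """
    if params.n_channels != volume.n_channels:
        raise ValueError("standardization params do not match volume channels")
    if model.config.input_channels != volume.n_channels:
        raise ValueError(
            f"model expects {model.config.input_channels} input channels, "
            f"volume has {volume.n_channels}"
        )
    std = standardize(volume, params)
    blocks = extract_blocks(std, grid)
    denoised = []
    for blk in blocks:
        residual = model.predict_residual(blk)
        denoised.append(blk + residual.astype(float))
    data = assemble_blocks(denoised, grid, volume.spatial_shape)
    out = std.like(data)
    return standardize(out, params, inverse=True)
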