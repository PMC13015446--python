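"""Scikit-learn-style estimator interface to the denoising runs.

The denoisers are fit/transform-shaped: ``fit`` trains the network(s) on a
:class:`~noise2average.volumes.RepetitionSet` (self-supervised — no clean
target is given except for :class:`SupervisedDenoiser`), after which
``denoised_`` holds the result and ``transform`` applies the trained model
to new volumes.  ``get_params``/``set_params`` come from sklearn's
BaseEstimator, so the classes compose with sklearn model selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .blocks import plan_blocks
from .engine import (
    IterationState,
    OracleDenoiser,
    RunConfig,
    noise2average_run,
    noise2noise_run,
    supervised_run,
)
from .network import (
    DenoiserModel,
    NetworkConfig,
    TrainingConfig,
    build_munet,
    denoise_volume,
)
from .volumes import RepetitionSet, Volume, compute_standardization

__all__ = ["Noise2AverageDenoiser", "Noise2NoiseDenoiser", "SupervisedDenoiser"]


class _BaseDenoiser(BaseEstimator):
    def __init__(self, depth=4, channels=8, use_batchnorm=False, loss="mse",
                 learning_rate=1e-3, epochs_per_iteration=10,
                 block_shape=(80, 80, 80), seed=0, model=None):
        self.depth = depth
        self.channels = channels
        self.use_batchnorm = use_batchnorm
        self.loss = loss
        self.learning_rate = learning_rate
        self.epochs_per_iteration = epochs_per_iteration
        self.block_shape = block_shape
        self.seed = seed
        self.model = model  # pretrained DenoiserModel or OracleDenoiser

    def _make_model(self, reps: RepetitionSet):
        if self.model is not None:
            return self.model
        ncfg = NetworkConfig(
            depth=self.depth, channels=self.channels,
            input_channels=reps.n_channels, output_channels=reps.n_channels,
            use_batchnorm=self.use_batchnorm,
        )
        return build_munet(ncfg, seed=self.seed)

    def _tcfg(self) -> TrainingConfig:
        return TrainingConfig(loss=self.loss, learning_rate=self.learning_rate,
                              epochs=self.epochs_per_iteration, seed=self.seed)

    def transform(self, volume: Volume, reps: RepetitionSet | None = None) -> Volume:
        """Denoise a single volume with the already-fitted model."""
        if not hasattr(self, "model_"):
            raise RuntimeError("call fit before transform")
        if isinstance(self.model_, OracleDenoiser):
            raise RuntimeError("oracle denoisers cannot transform new volumes")
        return denoise_volume(self.model_, volume, self.mask_, self.params_, self.grid_)


class Noise2AverageDenoiser(_BaseDenoiser):
    """Iterative self-supervised denoiser for multi-repetition volumes.

    Parameters follow the method's defaults: two iterations for a pair of
    repetitions and one otherwise (``iterations=None`` selects this rule),
    warm-started fine-tuning between iterations.

    Attributes (after ``fit``)
    --------------------------
    states_ : list of IterationState
    denoised_ : Volume — the last iteration's output.
    """

    def __init__(self, iterations=None, warm_start=True, networks_per="shared",
                 depth=4, channels=8, use_batchnorm=False, loss="mse",
                 learning_rate=1e-3, epochs_per_iteration=10,
                 block_shape=(80, 80, 80), seed=0, model=None):
        super().__init__(depth=depth, channels=channels, use_batchnorm=use_batchnorm,
                         loss=loss, learning_rate=learning_rate,
                         epochs_per_iteration=epochs_per_iteration,
                         block_shape=block_shape, seed=seed, model=model)
        self.iterations = iterations
        self.warm_start = warm_start
        self.networks_per = networks_per

    def fit(self, reps: RepetitionSet, y=None):
        iters = self.iterations
        if iters is None:
            iters = 2 if reps.n == 2 else 1
        cfg = RunConfig(iterations=iters, mode="n2a", networks_per=self.networks_per,
                        epochs_per_iteration=self.epochs_per_iteration,
                        warm_start=self.warm_start, block_shape=self.block_shape,
                        seed=self.seed)
        model = self._make_model(reps)
        self.states_ = noise2average_run(reps, model, cfg, self._tcfg())
        self.denoised_ = self.states_[-1].output
        self.model_ = model
        if not isinstance(model, OracleDenoiser):
            self.mask_ = reps.mask
            self.params_ = compute_standardization(reps.mean_volume(), reps.mask)
            self.grid_ = plan_blocks(reps.spatial_shape, self.block_shape)
        return self

    def fit_transform(self, reps: RepetitionSet, y=None) -> Volume:
        return self.fit(reps).denoised_


class Noise2NoiseDenoiser(_BaseDenoiser):
    """Noise-to-noise baseline: trains each repetition against another
    repetition (cyclic pairing) and averages the denoised repetitions."""

    def fit(self, reps: RepetitionSet, y=None):
        cfg = RunConfig(iterations=1, mode="n2n", block_shape=self.block_shape,
                        epochs_per_iteration=self.epochs_per_iteration, seed=self.seed)
        model = self._make_model(reps)
        self.denoised_ = noise2noise_run(reps, model, cfg, self._tcfg())
        self.model_ = model
        if not isinstance(model, OracleDenoiser):
            self.mask_ = reps.mask
            self.params_ = compute_standardization(reps.mean_volume(), reps.mask)
            self.grid_ = plan_blocks(reps.spatial_shape, self.block_shape)
        return self

    def fit_transform(self, reps: RepetitionSet, y=None) -> Volume:
        return self.fit(reps).denoised_


class SupervisedDenoiser(_BaseDenoiser):
    """Supervised upper bound: maps the repetition average to its residual
    against a clean reference (``y``) and denoises the average."""

    def fit(self, reps: RepetitionSet, y: Volume = None):
        if y is None:
            raise ValueError("SupervisedDenoiser requires the ground-truth volume as y")
        cfg = RunConfig(iterations=1, mode="supervised", block_shape=self.block_shape,
                        epochs_per_iteration=self.epochs_per_iteration, seed=self.seed)
        model = self._make_model(reps)
        self.denoised_ = supervised_run(reps, y, model, self._tcfg(), cfg)
        self.model_ = model
        if not isinstance(model, OracleDenoiser):
            self.mask_ = reps.mask
            self.params_ = compute_standardization(reps.mean_volume(), reps.mask)
            self.grid_ = plan_blocks(reps.spatial_shape, self.block_shape)
        return self

    def fit_transform(self, reps: RepetitionSet, y: Volume = None) -> Volume:
        return self.fit(reps, y).denoised_
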