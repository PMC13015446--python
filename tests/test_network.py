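"""MU-Net construction, masked losses, training, and blockwise inference."""

import numpy as np
import pytest

import noise2average as n2a
from noise2average.network import _loss_and_grad


class TestBuildMUNet:
    @pytest.mark.parametrize("depth", [2, 4, 10, 18])
    @pytest.mark.parametrize("channels", [4, 8])
    def test_shape_preservation_matrix(self, depth, channels):
        cfg = n2a.NetworkConfig(depth=depth, channels=channels,
                                input_channels=1, output_channels=1)
        model = n2a.build_munet(cfg, seed=0)
        out = model.predict_residual(np.random.default_rng(0).random((7, 8, 9, 1)))
        assert out.shape == (7, 8, 9, 1)
        assert np.all(np.isfinite(out))

    def test_receptive_field_formula_matches_impulse_response(self):
        """RF = 2*depth + 1: an impulse spreads to exactly that extent."""
        cfg = n2a.NetworkConfig(depth=4, channels=4, input_channels=1,
                                output_channels=1, zero_init_head=False)
        assert cfg.receptive_field == 9
        assert n2a.NetworkConfig(depth=18, channels=4).receptive_field == 37
        model = n2a.build_munet(cfg, seed=1)
        # perturbing the center voxel must only change outputs within RF/2
        x = np.random.default_rng(2).random((21, 21, 21, 1)).astype(np.float32)
        y0 = model.predict_residual(x)
        x2 = x.copy()
        x2[10, 10, 10, 0] += 1.0
        dy = np.abs(model.predict_residual(x2) - y0)[..., 0]
        nz = np.argwhere(dy > 1e-7)
        assert np.abs(nz - 10).max() <= 4  # half of (9 - 1)

    def test_deterministic_initialization(self):
        cfg = n2a.NetworkConfig(depth=4, channels=4)
        a = n2a.build_munet(cfg, seed=3)
        b = n2a.build_munet(cfg, seed=3)
        for (pa, _), (pb, _) in zip(a.net.parameters(), b.net.parameters()):
            assert np.array_equal(pa, pb)
        c = n2a.build_munet(cfg, seed=4)
        assert any(not np.array_equal(pa, pc)
                   for (pa, _), (pc, _) in zip(a.net.parameters(), c.net.parameters()))

    def test_parameter_count_deterministic_function_of_config(self):
        cfg = n2a.NetworkConfig(depth=4, channels=4, input_channels=2, output_channels=2)
        assert n2a.build_munet(cfg, seed=0).n_parameters == \
            n2a.build_munet(cfg, seed=99).n_parameters

    def test_diffusion_variant_constructs_and_runs(self):
        """Shallower wide variant with batch norm before every convolution."""
        cfg = n2a.NetworkConfig(depth=10, channels=192, input_channels=7,
                                output_channels=7, use_batchnorm=True)
        model = n2a.build_munet(cfg, seed=0)
        out = model.predict_residual(np.random.default_rng(0).random((8, 8, 8, 7)))
        assert out.shape == (8, 8, 8, 7)
        assert np.all(np.isfinite(out))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            n2a.NetworkConfig(depth=1)
        with pytest.raises(ValueError):
            n2a.NetworkConfig(channels=0)


class TestMaskedLoss:
    def test_zero_for_identical(self):
        x = np.random.default_rng(0).random((4, 4, 4, 1))
        m = np.ones((4, 4, 4), bool)
        assert n2a.masked_loss(x, x, m, "mse") == 0.0

    def test_half_mask_mae(self):
        pred = np.zeros((4, 4, 4, 1))
        tgt = np.zeros((4, 4, 4, 1))
        m = np.zeros((4, 4, 4), bool)
        m[:2] = True  # 32 masked voxels
        tgt[:1] = 1.0  # |diff| = 1 on exactly half of them
        assert n2a.masked_loss(pred, tgt, m, "mae") == pytest.approx(0.5)

    def test_mse_vs_mae_on_toy_mask(self):
        pred = np.zeros((3, 1, 1, 1))
        tgt = np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1, 1)
        m = np.ones((3, 1, 1), bool)
        assert n2a.masked_loss(pred, tgt, m, "mse") == pytest.approx(14 / 3)
        assert n2a.masked_loss(pred, tgt, m, "mae") == pytest.approx(2.0)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            n2a.masked_loss(np.zeros((2, 2, 2, 1)), np.zeros((3, 3, 3, 1)),
                            np.ones((2, 2, 2), bool))

    def test_gradient_matches_directional_finite_difference(self):
        rng = np.random.default_rng(0)
        pred = rng.random((5, 5, 5, 2))
        tgt = rng.random((5, 5, 5, 2))
        m = rng.random((5, 5, 5)) > 0.4
        for loss_type in ("mse", "mae"):
            l0, g = _loss_and_grad(pred, tgt, m, loss_type)
            eps = 1e-6
            lp, _ = _loss_and_grad(pred + eps * g, tgt, m, loss_type)
            lm, _ = _loss_and_grad(pred - eps * g, tgt, m, loss_type)
            fd = (lp - lm) / (2 * eps)
            assert fd == pytest.approx(float((g ** 2).sum()), rel=1e-4)


class TestTraining:
    def _zero_residual_pairs(self, n=4, size=16, seed=0):
        rng = np.random.default_rng(seed)
        pairs = []
        for _ in range(n):
            x = rng.standard_normal((size, size, size, 1)).astype(np.float32)
            pairs.append((x, np.zeros_like(x), np.ones((size,) * 3, bool)))
        return pairs

    def test_overfit_zero_residual_task(self):
        """Zero-residual targets on one 16^3 block: loss collapses in 50 epochs."""
        pairs = self._zero_residual_pairs(n=1) * 2  # same block twice: a split exists
        cfg = n2a.NetworkConfig(depth=2, channels=4, zero_init_head=False)
        model = n2a.build_munet(cfg, seed=1)
        tcfg = n2a.TrainingConfig(loss="mse", learning_rate=3e-2, epochs=50, seed=2)
        n2a.train_denoiser(model, pairs, tcfg)
        log = model.training_log
        assert log[-1]["train_loss"] <= log[0]["train_loss"]
        assert log[-1]["train_loss"] <= 1e-3

    def test_split_sizes(self):
        from noise2average.network import _split_epoch

        rng = np.random.default_rng(0)
        train, val = _split_epoch(10, 0.2, rng)
        assert len(train) == 8 and len(val) == 2
        train, val = _split_epoch(2, 0.2, rng)
        assert len(train) == 1 and len(val) == 1

    def test_monte_carlo_split_redrawn_each_epoch(self):
        from noise2average.network import _split_epoch

        rng = np.random.default_rng(0)
        draws = {tuple(sorted(_split_epoch(10, 0.2, rng)[1])) for _ in range(20)}
        assert len(draws) > 1  # validation membership varies across epochs

    def test_training_deterministic_under_seed(self):
        pairs = self._zero_residual_pairs(n=3, size=8)
        cfg = n2a.NetworkConfig(depth=2, channels=4)
        logs = []
        for _ in range(2):
            model = n2a.build_munet(cfg, seed=1)
            tcfg = n2a.TrainingConfig(loss="mse", learning_rate=1e-3, epochs=5, seed=7)
            n2a.train_denoiser(model, pairs, tcfg)
            logs.append([(r["train_loss"], r["val_loss"]) for r in model.training_log])
        assert logs[0] == logs[1]

    def test_loss_decreases_on_zero_residual(self):
        """First 10 epochs strictly improve in nearly all seeded runs."""
        wins = 0
        for seed in range(10):
            pairs = self._zero_residual_pairs(n=2, size=8, seed=seed)
            model = n2a.build_munet(
                n2a.NetworkConfig(depth=2, channels=4, zero_init_head=False), seed=seed)
            tcfg = n2a.TrainingConfig(loss="mse", learning_rate=1e-3, epochs=10, seed=seed)
            n2a.train_denoiser(model, pairs, tcfg)
            losses = [r["train_loss"] for r in model.training_log]
            wins += losses[-1] < losses[0]
        assert wins >= 9

    def test_too_few_pairs_rejected(self):
        model = n2a.build_munet(n2a.NetworkConfig(depth=2, channels=4), seed=0)
        with pytest.raises(ValueError):
            n2a.train_denoiser(model, self._zero_residual_pairs(n=1),
                               n2a.TrainingConfig(epochs=1))

    def test_checkpoint_round_trip(self, tmp_path):
        cfg = n2a.NetworkConfig(depth=4, channels=4, use_batchnorm=True)
        model = n2a.build_munet(cfg, seed=5)
        model.save(tmp_path / "ckpt.npz")
        loaded = n2a.DenoiserModel.load(tmp_path / "ckpt.npz")
        x = np.random.default_rng(0).random((6, 6, 6, 1))
        assert np.array_equal(model.predict_residual(x), loaded.predict_residual(x))


class _ZeroResidualModel:
    """Stub predicting an identically zero residual."""

    class config:
        input_channels = 1

    def predict_residual(self, block, training=False):
        return np.zeros_like(block)


class _ConstantResidualModel:
    def __init__(self, c):
        self.c = c

    class config:
        input_channels = 1

    def predict_residual(self, block, training=False):
        return np.full_like(block, self.c)


class TestDenoiseVolume:
    def _setup(self, shape=(20, 20, 20)):
        rng = np.random.default_rng(0)
        v = n2a.Volume(rng.normal(10, 3, shape))
        mask = n2a.BrainMask(np.ones(shape, bool))
        params = n2a.compute_standardization(v, mask)
        grid = n2a.plan_blocks(shape, (16, 16, 16))  # overlapping blocks
        return v, mask, params, grid

    def test_zero_residual_model_is_identity(self):
        v, mask, params, grid = self._setup()
        out = n2a.denoise_volume(_ZeroResidualModel(), v, mask, params, grid)
        assert np.allclose(out.data, v.data, rtol=1e-12, atol=1e-10)

    def test_constant_residual_no_seam_artifacts(self):
        """Overlapping blocks with equal residuals average seamlessly."""
        v, mask, params, grid = self._setup()
        assert grid.n_blocks == 8
        out = n2a.denoise_volume(_ConstantResidualModel(0.5), v, mask, params, grid)
        expected = v.data + 0.5 * params.std[0]
        assert np.allclose(out.data, expected, rtol=1e-10)

    def test_oracle_residual_restores_target(self):
        """A model predicting (target - input) exactly returns the target."""
        v, mask, params, grid = self._setup()
        rng = np.random.default_rng(1)
        target = n2a.Volume(v.data + rng.normal(0, 1, v.data.shape))
        target_std = n2a.standardize(target, params)

        class Oracle:
            class config:
                input_channels = 1

            def __init__(self):
                self.tgt_blocks = iter([])

            def predict_residual(self, block, training=False):
                # recover position by matching is impractical; use closure below
                raise NotImplementedError

        # simpler: apply the identity denoise pipeline to (target - v) residuals
        from noise2average.blocks import extract_blocks

        tgt_blocks = extract_blocks(target_std, grid)

        class SeqOracle:
            class config:
                input_channels = 1

            def __init__(self):
                self.i = 0

            def predict_residual(self, block, training=False):
                r = tgt_blocks[self.i] - block
                self.i += 1
                return r

        out = n2a.denoise_volume(SeqOracle(), v, mask, params, grid)
        assert np.allclose(out.data, target.data, rtol=1e-10, atol=1e-8)
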