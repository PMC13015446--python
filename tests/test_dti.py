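"""Tensor model synthesis/fit, DTI metrics, and encoding-scheme design."""

import numpy as np
import pytest

import noise2average as n2a
from noise2average.dti import load_bvecs_bvals, save_bvecs_bvals


def _uniform_field(shape, comps, s0=100.0):
    c = np.tile(np.asarray(comps, float), shape + (1,))
    return n2a.TensorField(c, np.full(shape, float(s0)))


class TestSynthesis:
    def test_b0_channel_equals_s0(self, tensor_phantom, seven_channel_scheme):
        dwi = n2a.synthesize_dwi(tensor_phantom.tensors, seven_channel_scheme)
        assert np.array_equal(dwi.data[..., 0], tensor_phantom.tensors.s0)

    def test_isotropic_closed_form(self):
        field = _uniform_field((4, 4, 4), [0.7, 0.7, 0.7, 0, 0, 0])
        scheme = n2a.DirectionSet([[1.0, 0, 0]], [1000.0])
        dwi = n2a.synthesize_dwi(field, scheme)
        assert dwi.data[0, 0, 0, 0] == pytest.approx(100 * np.exp(-0.7), rel=1e-12)

    def test_aligned_direction_sees_eigenvalue(self):
        field = _uniform_field((2, 2, 2), [1.7, 0.3, 0.3, 0, 0, 0])
        scheme = n2a.DirectionSet([[1.0, 0, 0], [0, 1.0, 0]], [1000.0, 1000.0])
        dwi = n2a.synthesize_dwi(field, scheme)
        assert dwi.data[0, 0, 0, 0] == pytest.approx(100 * np.exp(-1.7), rel=1e-12)
        assert dwi.data[0, 0, 0, 1] == pytest.approx(100 * np.exp(-0.3), rel=1e-12)


class TestOLSFit:
    def test_round_trip_noise_free(self, tensor_phantom, seven_channel_scheme):
        field = tensor_phantom.tensors
        dwi = n2a.synthesize_dwi(field, seven_channel_scheme)
        fit = n2a.fit_tensor_ols(dwi, seven_channel_scheme, tensor_phantom.mask)
        sel = tensor_phantom.mask.data
        scale = np.abs(field.components[sel]).max()
        err = np.abs(fit.components[sel] - field.components[sel]).max()
        assert err <= 1e-8 * scale
        assert np.allclose(fit.s0[sel], field.s0[sel], rtol=1e-8)

    def test_isotropic_eigenvalues_recovered(self, seven_channel_scheme):
        field = _uniform_field((4, 4, 4), [0.7, 0.7, 0.7, 0, 0, 0])
        dwi = n2a.synthesize_dwi(field, seven_channel_scheme)
        fit = n2a.fit_tensor_ols(dwi, seven_channel_scheme)
        met = n2a.tensor_metrics(fit)
        assert np.allclose(met.eigenvalues, 0.7, atol=1e-10)

    def test_rank_deficient_design_raises(self):
        # six coplanar directions + b0: cannot determine out-of-plane terms
        ang = np.linspace(0, np.pi, 6, endpoint=False)
        dirs = np.stack([np.cos(ang), np.sin(ang), np.zeros(6)], axis=1)
        dirs = np.vstack([[0, 0, 1.0], dirs])
        scheme = n2a.DirectionSet(dirs, [0.0] + [1000.0] * 6)
        dwi = n2a.Volume(np.full((2, 2, 2, 7), 100.0))
        with pytest.raises(ValueError, match="rank"):
            n2a.fit_tensor_ols(dwi, scheme)

    def test_md_unbiased_under_noise(self, seven_channel_scheme):
        """Monte-Carlo parameter recovery: mean MD within 2% of truth."""
        shape = (22, 22, 22)  # ~1e4 voxels
        field = _uniform_field(shape, [0.9, 0.7, 0.5, 0.05, 0.02, 0.01])
        dwi = n2a.synthesize_dwi(field, seven_channel_scheme)
        rng = np.random.default_rng(0)
        noisy = n2a.Volume(dwi.data + rng.standard_normal(dwi.data.shape) * 0.05 * 100)
        fit = n2a.fit_tensor_ols(noisy, seven_channel_scheme)
        md_true = (0.9 + 0.7 + 0.5) / 3
        assert n2a.tensor_metrics(fit).md.mean() == pytest.approx(md_true, rel=0.02)


class TestTensorMetrics:
    def test_isotropic(self):
        met = n2a.tensor_metrics(_uniform_field((2, 2, 2), [0.7, 0.7, 0.7, 0, 0, 0]))
        assert met.fa[0, 0, 0] == pytest.approx(0.0, abs=1e-12)
        for m in (met.md, met.ad, met.rd):
            assert m[0, 0, 0] == pytest.approx(0.7)

    def test_prolate_closed_form(self):
        met = n2a.tensor_metrics(_uniform_field((2, 2, 2), [1.7, 0.3, 0.3, 0, 0, 0]))
        lam = np.array([1.7, 0.3, 0.3])
        fa_expect = np.sqrt(1.5) * np.linalg.norm(lam - lam.mean()) / np.linalg.norm(lam)
        assert met.fa[0, 0, 0] == pytest.approx(fa_expect)  # ~0.799
        assert met.fa[0, 0, 0] == pytest.approx(0.799, abs=5e-4)
        assert met.md[0, 0, 0] == pytest.approx(0.7666666666, rel=1e-9)
        assert met.ad[0, 0, 0] == pytest.approx(1.7)
        assert met.rd[0, 0, 0] == pytest.approx(0.3)
        v1 = met.v1[0, 0, 0]
        assert abs(v1[0]) == pytest.approx(1.0)  # parallel to x, either sign

    def test_fa_limit_near_one(self):
        met = n2a.tensor_metrics(_uniform_field((1, 1, 1), [1.0, 1e-6, 1e-6, 0, 0, 0]))
        assert met.fa[0, 0, 0] > 0.999

    def test_fa_bounds_random_psd(self):
        rng = np.random.default_rng(4)
        a = rng.standard_normal((5, 5, 5, 3, 3))
        psd = a @ np.swapaxes(a, -1, -2)  # positive semidefinite
        comps = np.stack([psd[..., 0, 0], psd[..., 1, 1], psd[..., 2, 2],
                          psd[..., 0, 1], psd[..., 0, 2], psd[..., 1, 2]], axis=-1)
        met = n2a.tensor_metrics(n2a.TensorField(comps, np.ones((5, 5, 5))))
        assert (met.fa >= 0).all() and (met.fa <= 1 + 1e-12).all()


class TestConditionNumber:
    def test_coplanar_singular(self):
        ang = np.linspace(0, np.pi, 6, endpoint=False)
        dirs = np.stack([np.cos(ang), np.sin(ang), np.zeros(6)], axis=1)
        assert not np.isfinite(n2a.condition_number(dirs))

    def test_duplicate_direction_singular(self):
        rng = np.random.default_rng(0)
        dirs = rng.standard_normal((6, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        dirs[5] = dirs[0]
        assert not np.isfinite(n2a.condition_number(dirs))

    def test_kappa_at_least_one(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            dirs = rng.standard_normal((6, 3))
            dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
            assert n2a.condition_number(dirs) >= 1.0


class TestOptimizeDirections:
    def test_output_unit_norm_and_monotone(self):
        s1, q1 = n2a.optimize_directions(restarts=1, seed=0, polish_top=1, polish_rounds=1)
        s100, q100 = n2a.optimize_directions(restarts=20, seed=0, polish_top=5,
                                             polish_rounds=2)
        assert np.allclose(np.linalg.norm(s100.directions, axis=1), 1.0, atol=1e-8)
        assert q100.condition_number <= q1.condition_number
        assert q100.condition_number >= 1.0


class TestElectrostaticEnergy:
    def test_two_orthogonal(self):
        assert n2a.electrostatic_energy([[1, 0, 0], [0, 1, 0]]) == pytest.approx(np.sqrt(2))

    def test_antipodal_pair_infinite(self):
        assert not np.isfinite(n2a.electrostatic_energy([[1, 0, 0], [-1, 0, 0]]))

    def test_rotation_invariance(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(2)
        dirs = rng.standard_normal((8, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        e0 = n2a.electrostatic_energy(dirs)
        rot = Rotation.random(rng=rng).as_matrix()
        assert abs(n2a.electrostatic_energy(dirs @ rot.T) - e0) < 1e-10

    def test_closer_pair_increases_energy(self):
        base = np.array([[1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0]])
        closer = base.copy()
        closer[1] = [np.sin(0.5), np.cos(0.5), 0.0]  # moved toward the first
        assert n2a.electrostatic_energy(closer) > n2a.electrostatic_energy(base)


class TestSubsetSelection:
    @staticmethod
    def _fibonacci_pool(n=90):
        i = np.arange(n)
        phi = (1 + np.sqrt(5)) / 2
        z = (i + 0.5) / n
        th = 2 * np.pi * i / phi
        dirs = np.stack([np.sqrt(1 - z ** 2) * np.cos(th),
                         np.sqrt(1 - z ** 2) * np.sin(th), z], axis=1)
        return n2a.DirectionSet(dirs, np.full(n, 1000.0))

    def test_rotated_copy_is_selected(self, seven_channel_scheme):
        from scipy.spatial.transform import Rotation

        ref = n2a.DirectionSet(seven_channel_scheme.directions[1:],
                               seven_channel_scheme.bvalues[1:])
        rot = Rotation.random(rng=np.random.default_rng(5)).as_matrix()
        pool_dirs = np.vstack([self._fibonacci_pool(30).directions,
                               ref.directions @ rot.T])
        pool = n2a.DirectionSet(pool_dirs, np.full(36, 1000.0))
        subs = n2a.select_nearest_subsets(pool, ref, rotations=[rot],
                                          kappa_max=10.0)
        assert len(subs) == 1
        assert set(subs[0].tolist()) == set(range(30, 36))

    def test_kappa_and_distinctness_filters(self, seven_channel_scheme):
        ref = n2a.DirectionSet(seven_channel_scheme.directions[1:],
                               seven_channel_scheme.bvalues[1:])
        pool = self._fibonacci_pool(90)
        subs = n2a.select_nearest_subsets(pool, ref, n_rotations=200, seed=1)
        for s in subs:
            assert len(set(s.tolist())) == 6
            assert n2a.condition_number(pool.directions[s]) < 1.6

    def test_degenerate_pool_rejected(self, seven_channel_scheme):
        ref = n2a.DirectionSet(seven_channel_scheme.directions[1:],
                               seven_channel_scheme.bvalues[1:])
        # a pool of six near-identical directions: picks collapse to < 6 distinct
        base = np.array([0.0, 0.0, 1.0])
        dirs = np.stack([base + [1e-4 * k, 0, 0] for k in range(6)])
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        pool = n2a.DirectionSet(dirs, np.full(6, 1000.0))
        subs = n2a.select_nearest_subsets(pool, ref, n_rotations=50, seed=0)
        assert subs == []


class TestMinEnergyPair:
    def _pool_and_subsets(self):
        pool = TestSubsetSelection._fibonacci_pool(30)
        subsets = [np.arange(0, 6), np.arange(6, 12), np.arange(12, 18)]
        return pool, subsets

    def test_exhaustive_matches_brute_force(self):
        pool, subsets = self._pool_and_subsets()
        best = n2a.pick_min_energy_pair(subsets, pool)
        energies = {}
        for i in range(3):
            for j in range(i + 1, 3):
                dirs = np.vstack([pool.directions[subsets[i]], pool.directions[subsets[j]]])
                energies[(i, j)] = n2a.electrostatic_energy(dirs)
        assert best == min(energies, key=energies.get)

    def test_sampling_covers_exhaustive(self):
        pool, subsets = self._pool_and_subsets()
        assert n2a.pick_min_energy_pair(subsets, pool, n_trials=10, seed=0) == \
            n2a.pick_min_energy_pair(subsets, pool)

    def test_duplicate_subset_never_self_paired(self):
        pool, subsets = self._pool_and_subsets()
        dup = [subsets[0], subsets[0], subsets[1]]
        i, j = n2a.pick_min_energy_pair(dup, pool)
        # the identical pair (0, 1) has infinite energy and must be excluded
        assert not np.array_equal(dup[i], dup[j])

    def test_fewer_than_two_raises(self):
        pool, subsets = self._pool_and_subsets()
        with pytest.raises(ValueError):
            n2a.pick_min_energy_pair(subsets[:1], pool)


class TestBvecIO:
    def test_round_trip(self, tmp_path, seven_channel_scheme):
        save_bvecs_bvals(seven_channel_scheme, tmp_path / "bvecs", tmp_path / "bvals")
        loaded = load_bvecs_bvals(tmp_path / "bvecs", tmp_path / "bvals")
        assert np.allclose(loaded.directions, seven_channel_scheme.directions, atol=1e-9)
        assert np.allclose(loaded.bvalues, seven_channel_scheme.bvalues)
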