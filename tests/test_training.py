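"""Masked loss, augmentation group, LR schedule and loop reproducibility."""

import numpy as np
import pytest
from scipy.stats import chisquare

from cryoenhance.training import (
    ROTATIONS_24,
    LossSpec,
    LRSchedule,
    TrainingConfig,
    augment_pair,
    masked_mse,
    masked_mse_tensor,
    train,
)
from cryoenhance.network import ArchitectureConfig
from cryoenhance.nn import Tensor


class TestMaskedMSE:
    def test_identity_is_zero(self, rng):
        x = rng.random((2, 2, 2))
        assert masked_mse(x, x) == 0.0

    def test_hand_enumerated_single_survivor(self):
        # 2^3 block: one voxel disagrees with an all-zero target; the seven
        # (0, 0) voxels are masked, so N = 1 and the loss is 1^2 / 1
        x = np.zeros((2, 2, 2))
        x[0, 0, 0] = 1.0
        y = np.zeros((2, 2, 2))
        assert masked_mse(x, y, LossSpec(0.0)) == 1.0

    def test_hand_arithmetic_no_masking(self):
        assert masked_mse(np.array([1.0, 2.0]), np.array([3.0, 2.0])) == 2.0

    def test_fully_masked_returns_zero_not_nan(self):
        z = np.zeros((3, 3, 3))
        assert masked_mse(z, z) == 0.0

    def test_equals_plain_mse_without_zeros(self, rng):
        x = rng.random((4, 4, 4)) + 0.1
        y = rng.random((4, 4, 4)) + 0.1
        assert masked_mse(x, y) == pytest.approx(((x - y) ** 2).mean())

    def test_permutation_invariance(self, rng):
        x = rng.random(27)
        y = rng.random(27)
        y[rng.random(27) < 0.3] = 0.0
        perm = rng.permutation(27)
        assert masked_mse(x, y) == pytest.approx(masked_mse(x[perm], y[perm]))

    def test_tensor_version_matches_and_is_differentiable(self, rng):
        x = Tensor(rng.random((2, 3, 3, 3)), requires_grad=True)
        y = rng.random((2, 3, 3, 3))
        y[y < 0.4] = 0.0
        loss, n = masked_mse_tensor(x, y)
        assert float(loss.data) == pytest.approx(masked_mse(x.data, y))
        loss.backward()
        assert x.grad is not None

    def test_zero_tolerance_band(self):
        x = np.array([1e-7, 0.5])
        y = np.array([0.0, 0.5])
        # with a 1e-6 band the near-zero prediction is masked against a zero target
        assert masked_mse(x, y, LossSpec(1e-6)) == 0.0
        assert masked_mse(x, y, LossSpec(0.0)) > 0.0


class TestAugmentation:
    def test_identity_element_possible(self):
        a = np.arange(27.0).reshape(3, 3, 3)
        ident = [r for r in ROTATIONS_24
                 if r[0] == (0, 1, 2) and r[1] == (False, False, False)]
        assert len(ident) == 1

    def test_group_has_24_distinct_elements(self):
        a = np.arange(64.0).reshape(4, 4, 4)
        images = set()
        from cryoenhance.training import AugmentTransform

        for perm, flips in ROTATIONS_24:
            t = AugmentTransform(perm, flips, (False, False, False))
            images.add(t.apply(a).tobytes())
        assert len(images) == 24

    def test_inverse_recovers_original(self, rng):
        a = rng.random((5, 5, 5))
        b = rng.random((5, 5, 5))
        for seed in range(20):
            g = np.random.default_rng(seed)
            ai, bi, t = augment_pair(a, b, g)
            np.testing.assert_array_equal(t.invert(ai), a)
            np.testing.assert_array_equal(t.invert(bi), b)

    def test_same_transform_applied_to_both(self, rng):
        a = rng.random((4, 4, 4))
        ai, bi, t = augment_pair(a, a.copy(), np.random.default_rng(3))
        np.testing.assert_array_equal(ai, bi)

    def test_preserves_value_multiset_and_loss(self, rng):
        a = rng.random((4, 4, 4))
        b = rng.random((4, 4, 4))
        ai, bi, _ = augment_pair(a, b, np.random.default_rng(9))
        assert sorted(ai.ravel()) == sorted(a.ravel())
        assert masked_mse(ai, bi) == pytest.approx(masked_mse(a, b))

    def test_rotation_frequencies_uniform(self):
        # identify the drawn rotation by its action on an index-coded cube
        key_to_idx = {}
        a = np.arange(27.0).reshape(3, 3, 3)
        from cryoenhance.training import AugmentTransform

        for i, (perm, flips) in enumerate(ROTATIONS_24):
            t = AugmentTransform(perm, flips, (False, False, False))
            key_to_idx[t.apply(a).tobytes()] = i
        rng = np.random.default_rng(123)
        counts = np.zeros(24)
        for _ in range(10_000):
            ai, _, t = augment_pair(a, a, rng, rot90=True, flip=False)
            counts[key_to_idx[ai.tobytes()]] += 1
        _, p = chisquare(counts)
        assert p > 0.01


class TestLRSchedule:
    def test_monotone_improvement_keeps_lr(self):
        s = LRSchedule(lr=5e-4)
        for loss in (1.0, 0.9, 0.8):
            s.step(loss)
        assert s.lr == 5e-4

    def test_two_consecutive_failures_halve_once(self):
        s = LRSchedule(lr=5e-4)
        lrs = [s.step(loss) for loss in (1.0, 1.1, 1.2)]
        assert lrs == [5e-4, 5e-4, 2.5e-4]

    def test_floor_clamp(self):
        s = LRSchedule(lr=1.2e-5)
        s.step(1.0)
        s.step(1.1)
        assert s.step(1.2) == 1e-5
        s.step(1.3)
        assert s.step(1.4) == 1e-5

    def test_improvement_measured_against_running_best(self):
        # 1.0 then 1.5 (worse), 0.99 (better than best): counter resets
        s = LRSchedule(lr=4e-4)
        s.step(1.0)
        s.step(1.5)
        s.step(0.99)
        assert s.lr == 4e-4 and s.bad_count == 0

    def test_lr_sequence_non_increasing_random_losses(self, rng):
        s = LRSchedule(lr=5e-4)
        seq = [s.step(float(l)) for l in rng.random(50)]
        assert all(a >= b for a, b in zip(seq, seq[1:]))
        assert seq[-1] >= 1e-5


class TestTrainLoop:
    def _tiny_pairs(self, rng, n=6):
        pairs = []
        for _ in range(n):
            tgt = np.zeros((16, 16, 16), dtype=np.float32)
            tgt[4:12, 4:12, 4:12] = rng.random((8, 8, 8)).astype(np.float32)
            inp = tgt + 0.3 * rng.standard_normal(tgt.shape).astype(np.float32)
            pairs.append((inp, tgt))
        return pairs

    def test_seeded_runs_are_identical(self, rng):
        pairs = self._tiny_pairs(rng)
        arch = ArchitectureConfig(base_channels=8, input_edge=16)
        cfg = TrainingConfig(max_epochs=2, batch_size=2, seed=42, validate_every=1)
        h1 = train(pairs[:4], pairs[4:], arch, cfg).history
        h2 = train(pairs[:4], pairs[4:], arch, cfg).history
        np.testing.assert_allclose(h1.train_loss.values, h2.train_loss.values,
                                   rtol=1e-7)

    def test_fully_masked_targets_leave_parameters_unchanged(self):
        from cryoenhance.network import EnhancerNetwork

        zero = np.zeros((16, 16, 16), dtype=np.float32)
        pairs = [(zero, zero)] * 2
        arch = ArchitectureConfig(base_channels=8, input_edge=16)
        cfg = TrainingConfig(max_epochs=1, batch_size=2, seed=0,
                             loss=LossSpec(zero_tolerance=1e9))
        result = train(pairs, pairs, arch, cfg)
        assert (result.history.train_loss == 0).all()
        # reproduce the initialization train() performed: no step must have run
        init_rng = np.random.default_rng(cfg.seed)
        fresh = EnhancerNetwork(arch, seed=int(init_rng.integers(0, 2**31 - 1)))
        trained = dict(result.network.named_parameters())
        for name, p in fresh.named_parameters():
            np.testing.assert_array_equal(trained[name].data, p.data)

    def test_checkpoints_written(self, tmp_path, rng):
        pairs = self._tiny_pairs(rng, 4)
        arch = ArchitectureConfig(base_channels=8, input_edge=16)
        cfg = TrainingConfig(max_epochs=1, batch_size=2, seed=1, validate_every=1)
        train(pairs[:3], pairs[3:], arch, cfg, out_dir=tmp_path)
        assert (tmp_path / "best.npz").exists()
        assert (tmp_path / "final.npz").exists()
        assert (tmp_path / "history.csv").exists()
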