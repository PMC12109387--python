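"""Augmentation geometry, optimizer behavior, and training-loop contracts."""

import numpy as np
import pytest

from toothseg.io_formats import LabeledCloud, normalize_cloud
from toothseg.network import ModelConfig
from toothseg.synthetic import ArchSpec, generate_arch
from toothseg.training import TrainConfig, augment, split_dataset, train


def tiny_dataset(n=6, points=512, seed=0):
    clouds = []
    for i in range(n):
        c = generate_arch(ArchSpec(points_per_cloud=points, seed=seed + i))
        clouds.append(normalize_cloud(c)[0])
    return clouds


TINY_MODEL = dict(num_centers=24, k=6)


class TestAugment:
    def test_collapsed_ranges_are_identity(self, small_cloud):
        cfg = TrainConfig(
            rotation_deg=(0.0, 0.0), scale_range=(1.0, 1.0),
            translation_range=(0.0, 0.0),
        )
        out = augment(small_cloud, cfg, rng=0)
        assert np.allclose(out.points, small_cloud.points, atol=1e-12)
        assert np.array_equal(out.labels, small_cloud.labels)

    def test_rotation_preserves_pairwise_distances(self, small_cloud):
        cfg = TrainConfig(scale_range=(1.0, 1.0), translation_range=(0.0, 0.0))
        out = augment(small_cloud, cfg, rng=3)
        idx = np.arange(0, 200)
        d0 = np.linalg.norm(
            small_cloud.points[idx, None] - small_cloud.points[None, idx], axis=2
        )
        d1 = np.linalg.norm(out.points[idx, None] - out.points[None, idx], axis=2)
        assert np.allclose(d0, d1, atol=1e-6)

    def test_scale_multiplies_pairwise_distances(self, small_cloud):
        cfg = TrainConfig(rotation_deg=(0.0, 0.0), translation_range=(0.0, 0.0))
        gen = np.random.default_rng(11)
        expected_scale = np.random.default_rng(11).uniform(0.9, 1.1)
        out = augment(small_cloud, cfg, rng=gen)
        idx = np.arange(0, 100)
        d0 = np.linalg.norm(
            small_cloud.points[idx, None] - small_cloud.points[None, idx], axis=2
        )
        d1 = np.linalg.norm(out.points[idx, None] - out.points[None, idx], axis=2)
        ratio = d1[d0 > 0] / d0[d0 > 0]
        assert np.allclose(ratio, ratio[0], atol=1e-6)
        assert 0.9 <= ratio[0] <= 1.1

    def test_point_count_and_labels_untouched(self, small_cloud):
        out = augment(small_cloud, TrainConfig(), rng=5)
        assert len(out) == len(small_cloud)
        assert np.array_equal(out.labels, small_cloud.labels)

    def test_deterministic_per_seed(self, small_cloud):
        a = augment(small_cloud, TrainConfig(), rng=9)
        b = augment(small_cloud, TrainConfig(), rng=9)
        assert np.array_equal(a.points, b.points)

    def test_full_3d_rotation_is_rigid(self, small_cloud):
        cfg = TrainConfig(
            full_3d_rotation=True, scale_range=(1.0, 1.0),
            translation_range=(0.0, 0.0),
        )
        out = augment(small_cloud, cfg, rng=2)
        idx = np.arange(0, 100)
        d0 = np.linalg.norm(
            small_cloud.points[idx, None] - small_cloud.points[None, idx], axis=2
        )
        d1 = np.linalg.norm(out.points[idx, None] - out.points[None, idx], axis=2)
        assert np.allclose(d0, d1, atol=1e-6)

    def test_bad_ranges_rejected(self):
        with pytest.raises(ValueError, match="identity"):
            TrainConfig(scale_range=(1.2, 1.5))


class TestSplit:
    def test_70_15_15_partition(self):
        clouds = list(range(100))
        tr, va, te = split_dataset(clouds, seed=4)
        assert (len(tr), len(va), len(te)) == (70, 15, 15)
        assert sorted(tr + va + te) == clouds

    def test_seeded_shuffle_reproducible(self):
        clouds = list(range(40))
        assert split_dataset(clouds, seed=1) == split_dataset(clouds, seed=1)
        assert split_dataset(clouds, seed=1) != split_dataset(clouds, seed=2)


class TestTrainLoop:
    def test_zero_learning_rate_leaves_weights_unchanged(self):
        data = tiny_dataset(3)
        cfg = ModelConfig.desk_scale(**TINY_MODEL)
        tc = TrainConfig(learning_rate=0.0, max_epochs=1, seed=0,
                         points_supervised=128)
        from toothseg.network import SegModel

        model = SegModel(cfg, seed=5)
        before = [p.data.copy() for p in model.parameters()]
        train(data, [], cfg, tc, model=model)
        for b, p in zip(before, model.parameters()):
            assert np.array_equal(b, p.data)

    def test_patience_one_with_constant_metric_stops_after_two_epochs(self):
        from toothseg.network import SegModel

        data = tiny_dataset(3)
        cfg = ModelConfig.desk_scale(**TINY_MODEL)
        # zeroed head + lr=0 pins predictions (hence val mIoU) to a constant
        model = SegModel(cfg, seed=0)
        model.refine_out.weight.data[...] = 0.0
        model.refine_out.bias.data[...] = 0.0
        tc = TrainConfig(learning_rate=0.0, max_epochs=50, early_stop_patience=1,
                         seed=0, points_supervised=128, augment=False)
        res = train(data[:2], data[2:], cfg, tc, model=model)
        assert len(res.history) == 2
        assert res.best_epoch == 0

    def test_overfit_single_batch_loss_decreases(self):
        data = tiny_dataset(2, points=512)
        cfg = ModelConfig.desk_scale(**TINY_MODEL)
        tc = TrainConfig(learning_rate=1e-3, max_epochs=10, seed=2,
                         augment=False, points_supervised=512)
        res = train(data, [], cfg, tc)
        losses = [h["train_loss"] for h in res.history]
        assert all(b < a for a, b in zip(losses, losses[1:])), losses

    def test_same_seed_identical_history(self):
        data = tiny_dataset(4)
        cfg = ModelConfig.desk_scale(**TINY_MODEL)
        tc = TrainConfig(learning_rate=1e-3, max_epochs=3, seed=13,
                         points_supervised=128)
        h1 = train(data[:3], data[3:], cfg, tc).history
        h2 = train(data[:3], data[3:], cfg, tc).history
        for a, b in zip(h1, h2):
            assert abs(a["train_loss"] - b["train_loss"]) < 1e-6
            assert abs(a["val_miou"] - b["val_miou"]) < 1e-6

    def test_empty_dataset_raises(self):
        with pytest.raises(ValueError, match="empty"):
            train([], [], ModelConfig.desk_scale(**TINY_MODEL), TrainConfig())

    def test_history_records_expected_fields(self):
        data = tiny_dataset(3)
        cfg = ModelConfig.desk_scale(**TINY_MODEL)
        tc = TrainConfig(max_epochs=2, seed=0, points_supervised=128)
        res = train(data[:2], data[2:], cfg, tc)
        assert set(res.history[0]) == {"epoch", "train_loss", "val_loss", "val_miou"}
        assert res.best_val_miou == max(h["val_miou"] for h in res.history)
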