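"""Network blocks: shapes, analytic identities, and hand-computed oracles."""

import numpy as np
import pytest

from toothseg.autodiff import Tensor
from toothseg.io_formats import LabeledCloud
from toothseg.network import (
    AttentionPool,
    LocalFeatureExtractor,
    ModelConfig,
    MultiHeadSelfAttention,
    SegModel,
    cross_entropy_from_logits,
    cross_entropy_loss,
    fuse,
    interpolate_to_points,
    load_checkpoint,
    save_checkpoint,
    soft_pool,
)
from toothseg.preprocess import preprocess_cloud


@pytest.fixture(scope="module")
def tiny_model():
    return SegModel(ModelConfig.desk_scale(num_centers=32, k=8), seed=0)


class TestConfig:
    def test_default_dimensions(self):
        cfg = ModelConfig()
        assert cfg.num_centers == 2048
        assert cfg.k == 64
        assert cfg.d_model == 256 and cfg.attn_heads == 8 and cfg.head_dim == 32
        assert cfg.local_dim == 128
        assert cfg.num_classes == 33

    def test_rel_encoding_ablation_switches_layout(self):
        cfg = ModelConfig(use_rel_encoding=False)
        assert cfg.effective_layout == "abs_only"
        assert cfg.feature_width == 3

    def test_inconsistent_widths_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(local_dim=64)  # mlp_hidden still ends at 128


class TestLocalFeatures:
    def test_output_width_is_local_dim(self, rng):
        cfg = ModelConfig()
        block = LocalFeatureExtractor(7, cfg.mlp_hidden, rng)
        out = block(Tensor(rng.normal(size=(10, 5, 7))))
        assert out.shape == (10, 128)

    def test_identical_neighbors_equal_single_output(self, rng):
        block = LocalFeatureExtractor(4, (8, 16), rng)
        row = rng.normal(size=(1, 1, 4))
        rep = Tensor(np.tile(row, (1, 6, 1)))
        single = Tensor(row)
        assert np.allclose(block(rep).data, block(single).data, atol=1e-12)

    def test_neighbor_permutation_invariance(self, rng):
        block = LocalFeatureExtractor(4, (8, 16), rng)
        block.set_training(False)
        x = rng.normal(size=(3, 7, 4))
        perm = rng.permutation(7)
        assert np.allclose(
            block(Tensor(x)).data, block(Tensor(x[:, perm])).data, atol=1e-12
        )


class TestSelfAttention:
    def test_rows_of_attention_sum_to_one(self, rng):
        attn = MultiHeadSelfAttention(16, 4, 4, rng)
        a = attn.attention_matrices(Tensor(rng.normal(size=(9, 16))))
        assert a.shape == (4, 9, 9)
        assert np.allclose(a.sum(axis=-1), 1.0, atol=1e-5)

    def test_single_token_attention_is_identity_on_v(self, rng):
        attn = MultiHeadSelfAttention(8, 2, 4, rng)
        x = Tensor(rng.normal(size=(1, 8)))
        z = attn(x)
        v = x.data @ attn.w_v.data
        assert np.allclose(z.data, v, atol=1e-12)

    def test_two_token_closed_form(self, rng):
        """Identity projections, 2x2 tokens: compare to the direct softmax."""
        attn = MultiHeadSelfAttention(2, 1, 2, rng)
        for w in (attn.w_q, attn.w_k, attn.w_v):
            w.data[...] = np.eye(2)
        x = np.array([[1.0, 0.0], [0.0, 1.0]])
        z = attn(Tensor(x)).data
        scale = np.sqrt(2.0)
        scores = x @ x.T / scale
        e = np.exp(scores - scores.max(axis=1, keepdims=True))
        a = e / e.sum(axis=1, keepdims=True)
        assert np.allclose(z, a @ x, atol=1e-12)

    def test_dmodel_scale_mode_divides_by_dmodel(self, rng):
        attn = MultiHeadSelfAttention(8, 2, 4, rng, scale_mode="dmodel")
        assert attn.scale == 8.0

    def test_output_width_is_heads_times_head_dim(self, rng):
        attn = MultiHeadSelfAttention(256, 8, 32, rng)
        z = attn(Tensor(rng.normal(size=(5, 256))))
        assert z.shape == (5, 256)


class TestPooling:
    def test_attention_pool_uniform_on_identical_rows(self, rng):
        pool = AttentionPool(6, rng)
        row = rng.normal(size=6)
        x = Tensor(np.tile(row, (5, 1)))
        alpha = pool.weights(x).data
        assert np.allclose(alpha, 0.2, atol=1e-12)
        assert np.allclose(pool(x).data, row, atol=1e-12)

    def test_attention_pool_single_row(self, rng):
        pool = AttentionPool(4, rng)
        x = rng.normal(size=(1, 4))
        assert np.allclose(pool(Tensor(x)).data, x[0], atol=1e-12)

    def test_attention_pool_weights_sum_to_one(self, rng):
        pool = AttentionPool(8, rng)
        alpha = pool.weights(Tensor(rng.normal(size=(20, 8)) * 10)).data
        assert np.isclose(alpha.sum(), 1.0, atol=1e-5)

    def test_attention_pool_saturates_to_dominant_row(self, rng):
        pool = AttentionPool(2, rng)
        pool.weight.data[...] = np.array([[1.0], [0.0]])
        x = np.array([[100.0, 5.0], [0.0, -3.0], [0.0, 2.0]])  # score gap 100
        out = pool(Tensor(x)).data
        assert np.allclose(out, x[0], atol=1e-6)

    def test_soft_pool_identical_rows(self, rng):
        row = rng.normal(size=5)
        out = soft_pool(Tensor(np.tile(row, (7, 1))))
        assert np.allclose(out.data, row, atol=1e-12)

    def test_soft_pool_single_row(self, rng):
        x = rng.normal(size=(1, 5))
        assert np.allclose(soft_pool(Tensor(x)).data, x[0], atol=1e-12)

    def test_soft_pool_two_value_closed_form(self):
        # channel values {0, ln 3}: weights {1, 3}/4 -> (0 + 3 ln 3)/4
        x = Tensor(np.array([[0.0], [np.log(3.0)]]))
        assert np.isclose(soft_pool(x).data[0], 3 * np.log(3.0) / 4, atol=1e-12)

    def test_soft_pool_overflow_guarded(self):
        x = Tensor(np.array([[1000.0], [999.0]]))
        out = soft_pool(x).data
        assert np.isfinite(out).all()


class TestFuse:
    def test_width_is_sum(self, rng):
        out = fuse(Tensor(rng.normal(size=(4, 128))), Tensor(rng.normal(size=256)))
        assert out.shape == (4, 384)

    def test_local_block_preserved_when_global_zero(self, rng):
        local = rng.normal(size=(4, 6))
        out = fuse(Tensor(local), Tensor(np.zeros(3)))
        assert np.allclose(out.data[:, :6], local)
        assert np.allclose(out.data[:, 6:], 0.0)

    def test_order_local_then_global(self, rng):
        g = np.arange(3.0)
        out = fuse(Tensor(np.zeros((2, 2))), Tensor(g))
        assert np.allclose(out.data, [[0, 0, 0, 1, 2]] * 2)


class TestSegment:
    def test_probability_rows_sum_to_one(self, tiny_model, small_cloud):
        out = tiny_model.segment(small_cloud)
        assert out.probabilities.shape == (len(small_cloud), 33)
        assert np.allclose(out.probabilities.sum(axis=1), 1.0, atol=1e-5)
        assert (out.probabilities >= 0).all()

    def test_zeroed_head_gives_uniform(self, small_cloud):
        model = SegModel(ModelConfig.desk_scale(num_centers=16, k=4), seed=1)
        model.refine_out.weight.data[...] = 0.0
        model.refine_out.bias.data[...] = 0.0
        out = model.segment(small_cloud)
        assert np.allclose(out.probabilities, 1.0 / 33, atol=1e-12)
        assert (out.labels == 0).all()  # argmax tie-break to lowest class

    def test_point_coincident_with_center_gets_center_distribution(self, rng):
        centers = rng.normal(size=(5, 3))
        vals = rng.normal(size=(5, 4))
        pts = np.vstack([centers[2], rng.normal(size=(3, 3))])
        out = interpolate_to_points(pts, centers, vals, n_neighbors=3)
        assert np.allclose(out[0], vals[2], atol=0)

    def test_permutation_equivariance_with_fixed_centers(self, small_cloud, rng):
        model = SegModel(ModelConfig.desk_scale(num_centers=32, k=8), seed=3)
        centers = np.arange(32) * 7 % len(small_cloud)
        out = model.segment(small_cloud, center_indices=centers)
        perm = rng.permutation(len(small_cloud))
        inv = np.empty_like(perm)
        inv[perm] = np.arange(len(perm))
        permuted = LabeledCloud(small_cloud.points[perm], class_count=33)
        out_p = model.segment(permuted, center_indices=inv[centers])
        assert np.allclose(out_p.probabilities, out.probabilities[perm], atol=1e-8)


class TestAblations:
    @pytest.mark.parametrize(
        "flags",
        [
            {},
            {"use_rel_encoding": False},
            {"use_attention_pooling": False},
            {"use_transformer": False},
        ],
        ids=["full", "no-rel-encoding", "no-attn-pool", "no-transformer"],
    )
    def test_all_variants_run_forward(self, small_cloud, flags):
        cfg = ModelConfig.desk_scale(num_centers=24, k=6, **flags)
        model = SegModel(cfg, seed=0)
        out = model.segment(small_cloud)
        assert out.labels.shape == (len(small_cloud),)
        assert np.allclose(out.probabilities.sum(axis=1), 1.0, atol=1e-5)

    def test_no_transformer_has_no_attention_params(self):
        cfg = ModelConfig.desk_scale(use_transformer=False)
        model = SegModel(cfg, seed=0)
        names = [n for n, _ in model.named_parameters()]
        assert not any("attention" in n or n.startswith("proj") for n in names)


class TestCrossEntropy:
    def test_perfect_one_hot_is_zero(self):
        probs = np.eye(4)
        assert cross_entropy_loss(probs, np.arange(4)) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_prediction_is_log_c(self):
        probs = np.full((10, 33), 1.0 / 33)
        labels = np.arange(10) % 33
        assert cross_entropy_loss(probs, labels) == pytest.approx(np.log(33), abs=1e-12)

    def test_hand_computed_two_points(self):
        probs = np.array([[0.9, 0.1], [0.2, 0.8]])
        expected = -(np.log(0.9) + np.log(0.8)) / 2
        assert cross_entropy_loss(probs, [0, 1]) == pytest.approx(expected, abs=1e-12)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            cross_entropy_loss(np.ones((3, 2)) / 2, [0, 1])

    def test_logit_version_matches_probability_version(self, rng):
        logits = rng.normal(size=(20, 5))
        labels = rng.integers(0, 5, size=20)
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        probs = e / e.sum(axis=1, keepdims=True)
        a = cross_entropy_from_logits(Tensor(logits), labels).data
        assert np.isclose(a, cross_entropy_loss(probs, labels), atol=1e-12)


class TestCheckpoint:
    def test_roundtrip_preserves_predictions(self, tmp_path, tiny_model, small_cloud):
        out = tiny_model.segment(small_cloud)
        p = tmp_path / "ckpt.npz"
        save_checkpoint(tiny_model, p)
        back = load_checkpoint(p)
        assert back.config == tiny_model.config
        out2 = back.segment(small_cloud)
        assert np.allclose(out2.probabilities, out.probabilities, atol=0)
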