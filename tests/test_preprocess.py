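"""FPS, k-NN grouping and relative encoding against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from toothseg.preprocess import (
    farthest_point_sampling,
    knn_group,
    preprocess_cloud,
    relative_encoding,
)


def fps_oracle(points: np.ndarray, m: int, start: int) -> list[int]:
    """Exhaustive greedy max-min reference (O(N·m), lowest-index ties)."""
    selected = [start]
    for _ in range(m - 1):
        best, best_d = None, -1.0
        for j in range(len(points)):
            if j in selected:
                continue
            dj = min(np.linalg.norm(points[j] - points[s]) for s in selected)
            if dj > best_d + 1e-15:
                best, best_d = j, dj
        selected.append(best)
    return selected


def knn_oracle(points: np.ndarray, center: int, k: int) -> list[int]:
    d = np.linalg.norm(points - points[center], axis=1)
    return sorted(range(len(points)), key=lambda j: (d[j], j))[:k]


class TestFPS:
    def test_collinear_picks_extremes(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float)
        res = farthest_point_sampling(pts, 2, start_index=0)
        assert set(res.center_indices) == {0, 3}

    def test_m_equals_n_selects_all(self, rng):
        pts = rng.normal(size=(10, 3))
        res = farthest_point_sampling(pts, 10)
        assert sorted(res.center_indices) == list(range(10))

    def test_m_one_is_start(self):
        pts = np.eye(3)
        res = farthest_point_sampling(pts, 1, start_index=2)
        assert list(res.center_indices) == [2]

    def test_m_too_large_raises(self, rng):
        with pytest.raises(ValueError):
            farthest_point_sampling(rng.normal(size=(4, 3)), 5)

    def test_seeded_random_start_is_deterministic(self, rng):
        pts = rng.normal(size=(30, 3))
        a = farthest_point_sampling(pts, 5, start_index=None, seed=9)
        b = farthest_point_sampling(pts, 5, start_index=None, seed=9)
        assert np.array_equal(a.center_indices, b.center_indices)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(2, 24))
    def test_matches_exhaustive_oracle(self, seed, n):
        gen = np.random.default_rng(seed)
        pts = gen.normal(size=(n, 3))
        m = int(gen.integers(1, n + 1))
        got = farthest_point_sampling(pts, m, start_index=0).center_indices
        assert list(got) == fps_oracle(pts, m, 0)

    def test_min_pairwise_distance_nonincreasing_in_m(self, rng):
        pts = rng.normal(size=(40, 3))
        prev = np.inf
        for m in range(2, 20):
            idx = farthest_point_sampling(pts, m).center_indices
            sel = pts[idx]
            d = np.linalg.norm(sel[:, None] - sel[None, :], axis=2)
            np.fill_diagonal(d, np.inf)
            cur = d.min()
            assert cur <= prev + 1e-12
            prev = cur


class TestKnn:
    def test_hand_example(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [3, 0, 0]], dtype=float)
        got = knn_group(pts, np.array([0]), 2)
        assert list(got[0]) == [0, 1]

    def test_k_equals_n_sorted_by_distance(self, rng):
        pts = rng.normal(size=(12, 3))
        got = knn_group(pts, np.array([4]), 12)[0]
        d = np.linalg.norm(pts - pts[4], axis=1)
        assert np.all(np.diff(d[got]) >= -1e-12)
        assert sorted(got) == list(range(12))

    def test_coincident_duplicates_selected_first(self):
        pts = np.array([[0, 0, 0], [5, 0, 0], [0, 0, 0], [1, 0, 0]], dtype=float)
        got = knn_group(pts, np.array([0]), 3)[0]
        assert list(got) == [0, 2, 3]  # both zero-distance points before d=1

    def test_k_too_large_raises(self, rng):
        with pytest.raises(ValueError):
            knn_group(rng.normal(size=(3, 3)), np.array([0]), 4)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_bruteforce_oracle(self, seed):
        gen = np.random.default_rng(seed)
        n = int(gen.integers(2, 128))
        pts = gen.normal(size=(n, 3))
        k = int(gen.integers(1, n + 1))
        centers = gen.choice(n, size=min(4, n), replace=False)
        got = knn_group(pts, centers, k)
        for row, c in zip(got, centers):
            assert list(row) == knn_oracle(pts, c, k)


class TestRelativeEncoding:
    def test_self_neighbor_is_zero(self, rng):
        pts = rng.normal(size=(5, 3))
        enc = relative_encoding(pts, np.array([2]), np.array([[2, 0]]))
        assert np.allclose(enc.rel_pos[0, 0], 0.0)
        assert enc.dist[0, 0] == 0.0

    def test_hand_computed_offset_and_distance(self):
        pts = np.array([[0, 0, 0], [1, 2, 2]], dtype=float)
        enc = relative_encoding(pts, np.array([0]), np.array([[0, 1]]))
        assert np.allclose(enc.rel_pos[0, 1], [1, 2, 2])
        assert np.isclose(enc.dist[0, 1], 3.0)

    def test_dist_is_norm_of_rel(self, rng):
        pts = rng.normal(size=(64, 3))
        _, enc = preprocess_cloud(pts, 16, 8)
        assert np.allclose(enc.dist, np.linalg.norm(enc.rel_pos, axis=2), atol=1e-6)

    def test_translation_invariance(self, rng):
        pts = rng.normal(size=(40, 3))
        centers = np.arange(5)
        neigh = knn_group(pts, centers, 6)
        a = relative_encoding(pts, centers, neigh)
        b = relative_encoding(pts + np.array([3.0, -7.0, 11.0]), centers, neigh)
        assert np.allclose(a.rel_pos, b.rel_pos, atol=1e-9)
        assert np.allclose(a.dist, b.dist, atol=1e-9)

    def test_rotation_covariance_and_distance_invariance(self, rng):
        pts = rng.normal(size=(40, 3))
        theta = 0.7
        rot = np.array([
            [np.cos(theta), -np.sin(theta), 0],
            [np.sin(theta), np.cos(theta), 0],
            [0, 0, 1.0],
        ])
        centers = np.arange(6)
        neigh = knn_group(pts, centers, 5)
        a = relative_encoding(pts, centers, neigh)
        b = relative_encoding(pts @ rot.T, centers, neigh)
        assert np.allclose(b.rel_pos, a.rel_pos @ rot.T, atol=1e-6)
        assert np.allclose(b.dist, a.dist, atol=1e-6)

    @pytest.mark.parametrize(
        "layout,width", [("rel_dist_abs", 7), ("rel_dist", 4), ("abs_only", 3)]
    )
    def test_layout_widths(self, rng, layout, width):
        pts = rng.normal(size=(30, 3))
        _, enc = preprocess_cloud(pts, 8, 4, layout=layout)
        assert enc.features.shape == (8, 4, width)

    def test_unknown_layout_raises(self, rng):
        pts = rng.normal(size=(10, 3))
        with pytest.raises(ValueError, match="layout"):
            relative_encoding(pts, np.array([0]), np.array([[0]]), layout="huh")


def test_preprocess_clamps_centers_to_cloud_size(rng, caplog):
    pts = rng.normal(size=(20, 3))
    sampling, enc = preprocess_cloud(pts, 2048, 8)
    assert sampling.m == 20
    assert enc.features.shape[0] == 20
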