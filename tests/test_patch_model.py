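import numpy as np
import pytest
from sklearn.decomposition import PCA

from agesal.patch_model import (
    PatchFeatureMatrix,
    PatchGrid,
    extract_patch_features,
    multiscale_patch_saliency,
    patch_saliency,
    patch_saliency_scores_naive,
    pca_reduce,
)


class TestExtractPatchFeatures:
    def test_counts_and_dimension(self):
        rng = np.random.default_rng(0)
        grid, X = extract_patch_features(rng.random((64, 64, 3)), 16)
        assert grid.n_p == 16
        assert X.shape == (5 * 16 * 16, 16)

    def test_constant_image_identical_features_zero_gradients(self):
        img = np.full((64, 64, 3), 0.4)
        grid, X = extract_patch_features(img, 16)
        assert np.ptp(X, axis=1).max() < 1e-12
        # gradient planes are the last 2*t^2 entries of each vector
        assert np.all(X[3 * 256:, :] == 0)

    def test_checkerboard_gives_two_alternating_vectors(self):
        img = np.zeros((64, 64, 3))
        for pr in range(4):
            for pc in range(4):
                if (pr + pc) % 2 == 0:
                    img[pr * 16:(pr + 1) * 16, pc * 16:(pc + 1) * 16] = 0.9
        _, X = extract_patch_features(img, 16)
        even = [i for i in range(16) if (i // 4 + i % 4) % 2 == 0]
        odd = [i for i in range(16) if (i // 4 + i % 4) % 2 == 1]
        # color planes (first 3*t^2 entries) alternate between exactly two
        # vectors; gradient planes differ at image borders and are excluded
        color = X[: 3 * 256]
        for group in (even, odd):
            assert np.ptp(color[:, group], axis=1).max() < 1e-9
        assert np.abs(color[:, even[0]] - color[:, odd[0]]).max() > 1

    def test_remainder_cropped(self):
        grid, X = extract_patch_features(np.zeros((70, 40, 3)), 16)
        assert (grid.n_rows, grid.n_cols) == (4, 2)

    def test_oversized_patch_rejected(self):
        with pytest.raises(ValueError):
            extract_patch_features(np.zeros((32, 32, 3)), 64)
        with pytest.raises(ValueError):
            extract_patch_features(np.zeros((64, 64, 3)), 10)


class TestPcaReduce:
    def test_full_variance_projection_is_isometric(self):
        rng = np.random.default_rng(1)
        X = rng.random((40, 20))
        red = pca_reduce(X, variance_keep=1.0)
        Xc = X - X.mean(axis=1, keepdims=True)
        from scipy.spatial.distance import pdist
        np.testing.assert_allclose(pdist(red.X_reduced.T), pdist(Xc.T),
                                   rtol=1e-6)

    def test_identical_patches_degenerate(self):
        X = np.tile(np.arange(10.0)[:, None], (1, 5))
        red = pca_reduce(X)
        assert red.d == 0 and red.degenerate

    def test_constructed_rank2_spectrum_keeps_one_component(self):
        # scores along two orthogonal directions with sample variances
        # exactly 9 and 1: cumulative share of the first component is
        # 9/10, so variance_keep=0.9 retains d=1
        a0 = np.sqrt(27 / 4)  # var((a0,-a0,a0,-a0)) = 4*a0^2/3 = 9
        b0 = np.sqrt(3 / 4)
        X = np.zeros((6, 4))
        X[0] = [a0, -a0, a0, -a0]
        X[1] = [b0, b0, -b0, -b0]
        red = pca_reduce(X, variance_keep=0.9)
        np.testing.assert_allclose(red.eigvals[:2], [9.0, 1.0], rtol=1e-12)
        assert red.d == 1

    def test_eigvals_match_sklearn_pca(self):
        rng = np.random.default_rng(3)
        X = rng.random((12, 30))
        red = pca_reduce(X, variance_keep=1.0)
        sk = PCA().fit(X.T)
        np.testing.assert_allclose(red.eigvals[:len(sk.explained_variance_)],
                                   sk.explained_variance_, rtol=1e-9)


def _toy_grid(centers, image_shape, t=8):
    n = len(centers)
    return PatchGrid(t=t, n_rows=1, n_cols=n,
                     centers=np.asarray(centers, dtype=float),
                     image_shape=image_shape)


def _reduced(coords):
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    return PatchFeatureMatrix(X=coords, eigvals=np.ones(coords.shape[0]),
                              basis=np.eye(coords.shape[0]),
                              d=coords.shape[0], X_reduced=coords)


class TestPatchSaliency:
    def test_two_patch_hand_value(self):
        # |x1-x2| = 3, patch centers separated by the full image diagonal
        # => normalized dist 1 => S = 3 / (1+1) = 3/2 for both patches
        h = w = 10
        diag = np.hypot(h, w)
        grid = _toy_grid([(0.0, 0.0), (h, w)], (h, w))
        ps = patch_saliency(grid, _reduced([[0.0, 3.0]]), smooth_sigma=0)
        np.testing.assert_allclose(ps.scores, [1.5, 1.5])

    def test_homogeneous_patches_all_zero(self):
        grid = _toy_grid([(4, 4), (4, 12), (4, 20)], (8, 24))
        ps = patch_saliency(grid, _reduced([[1.0, 1.0, 1.0]]),
                            smooth_sigma=0)
        np.testing.assert_allclose(ps.scores, 0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        n_rows, n_cols, t = 4, 6, 8
        centers = np.array([(r * t + 3.5, c * t + 3.5)
                            for r in range(n_rows) for c in range(n_cols)])
        grid = PatchGrid(t=t, n_rows=n_rows, n_cols=n_cols, centers=centers,
                         image_shape=(n_rows * t, n_cols * t))
        coords = rng.random((3, n_rows * n_cols))
        red = _reduced(coords)
        wk = float(rng.uniform(0, 1))
        ps = patch_saliency(grid, red, w_k=wk, smooth_sigma=0)
        naive = patch_saliency_scores_naive(coords, centers,
                                            grid.image_shape, w_k=wk)
        np.testing.assert_allclose(ps.scores, naive, rtol=1e-9)

    def test_anomalous_patch_ranked_first(self):
        img = np.full((32, 32, 3), 0.5)
        img[8:16, 16:24] = (0.9, 0.1, 0.1)  # one odd patch in a 4x4 grid
        grid, X = extract_patch_features(img, 8)
        red = pca_reduce(X)
        ps = patch_saliency(grid, red, smooth_sigma=0)
        assert np.argmax(ps.scores) == 1 * 4 + 2

    def test_degenerate_reduction_gives_flat_map(self):
        grid = _toy_grid([(4, 4), (4, 12)], (8, 16))
        empty = PatchFeatureMatrix(X=np.zeros((4, 2)), eigvals=np.zeros(4),
                                   basis=np.zeros((4, 0)), d=0,
                                   X_reduced=np.zeros((0, 2)),
                                   degenerate=True)
        ps = patch_saliency(grid, empty)
        assert ps.degenerate and np.all(ps.map.grid == 0)


class TestMultiscale:
    def test_singleton_subset_equals_single_size_map(self):
        rng = np.random.default_rng(4)
        img = rng.random((64, 64, 3))
        combined = multiscale_patch_saliency(img, (16,))
        grid, X = extract_patch_features(img, 16)
        single = patch_saliency(grid, pca_reduce(X), smooth_sigma=8.0)
        np.testing.assert_allclose(combined.grid, single.map.grid,
                                   atol=1e-12)

    def test_subsets_differ_only_by_extra_scale(self):
        rng = np.random.default_rng(5)
        img = rng.random((128, 128, 3))
        full = multiscale_patch_saliency(img, (64, 32, 16, 8))
        partial = multiscale_patch_saliency(img, (32, 16, 8))
        assert full.grid.shape == partial.grid.shape
        assert np.abs(full.grid - partial.grid).max() > 0

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            multiscale_patch_saliency(np.zeros((64, 64, 3)), ())
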