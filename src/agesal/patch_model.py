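"""PCA patch-dissimilarity saliency ("P") with age-adapted patch sizes.

The image is tiled into non-overlapping t x t patches (t from
{64, 32, 16, 8}; any trailing remainder is cropped).  Each patch is a
feature vector of its flattened CIELAB channels (L*, a*, b*) and horizontal
and vertical intensity-gradient planes, 5*t^2 values.  PCA reduces the
patch vectors to the leading components holding a given variance fraction,
and a patch's saliency is its spatially-weighted dissimilarity to the other
patches:

    S(R_i) = omega(i) * sum_j  ||x_i - x_j||_1 / (1 + dist(p_i, p_j))

with patch-center distances normalized by the image diagonal and omega an
optional center weighting 1 - w_k * d(c, p_i)/D.  Age adaptation selects a
subset of patch sizes — scale indices 1..4 map to t = 64, 32, 16, 8
(coarser to finer) — and averages the per-size maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist, pdist, squareform
from skimage.color import rgb2lab

from agesal.gaze_data import SaliencyMap, minmax_normalize

PATCH_SIZES = (64, 32, 16, 8)  # scale index 1..4, coarser -> finer
DEFAULT_VARIANCE_KEEP = 0.95


@dataclass
class PatchGrid:
    """Non-overlapping t x t tiling of the (cropped) image."""

    t: int
    n_rows: int
    n_cols: int
    centers: np.ndarray  # (n_p, 2) of (row, col) patch centers, pixels
    image_shape: tuple[int, int]

    @property
    def n_p(self) -> int:
        return self.n_rows * self.n_cols


@dataclass
class PatchFeatureMatrix:
    """Per-patch feature vectors and their PCA reduction.

    ``X`` is (feature_dim, n_p); ``eigvals`` are the covariance eigenvalues
    in descending order, ``basis`` the top-d eigenvectors (feature_dim, d),
    and ``X_reduced`` the (d, n_p) projection of the centered features.
    ``d = 0`` flags a zero-variance (degenerate) patch set.
    """

    X: np.ndarray
    eigvals: np.ndarray
    basis: np.ndarray
    d: int
    X_reduced: np.ndarray
    degenerate: bool = False


@dataclass
class PatchSaliency:
    """Per-patch dissimilarity scores and the rendered full-resolution map."""

    scores: np.ndarray
    map: SaliencyMap
    grid: PatchGrid
    degenerate: bool = False


def extract_patch_features(image: np.ndarray, t: int
                           ) -> tuple[PatchGrid, np.ndarray]:
    """Tile the image into t x t patches and build per-patch vectors.

    Each patch vector concatenates the flattened L*, a*, b* planes and the
    horizontal (I_x) and vertical (I_y) intensity gradients: 5*t^2 values.
    Trailing rows/columns that do not fill a patch are cropped.
    """
    if t not in PATCH_SIZES:
        raise ValueError(f"patch size must be one of {PATCH_SIZES}, got {t}")
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        image = np.stack([image] * 3, axis=-1)
    h, w = image.shape[:2]
    if t > min(h, w):
        raise ValueError(f"patch size {t} exceeds image dims {h}x{w}")
    if image.max() > 1.0:
        image = image / 255.0

    n_rows, n_cols = h // t, w // t
    crop = image[: n_rows * t, : n_cols * t, :3]
    lab = rgb2lab(crop)
    intensity = crop.mean(axis=-1)
    iy, ix = np.gradient(intensity)

    planes = [lab[..., 0], lab[..., 1], lab[..., 2], ix, iy]
    feats = []
    centers = []
    for pr in range(n_rows):
        for pc in range(n_cols):
            sl = (slice(pr * t, (pr + 1) * t), slice(pc * t, (pc + 1) * t))
            feats.append(np.concatenate([p[sl].ravel() for p in planes]))
            centers.append((pr * t + (t - 1) / 2.0, pc * t + (t - 1) / 2.0))
    grid = PatchGrid(t=t, n_rows=n_rows, n_cols=n_cols,
                     centers=np.asarray(centers), image_shape=(h, w))
    return grid, np.asarray(feats).T


def pca_reduce(X: np.ndarray,
               variance_keep: float = DEFAULT_VARIANCE_KEEP
               ) -> PatchFeatureMatrix:
    """Project centered patch vectors onto their leading principal axes.

    ``d`` is the smallest component count whose cumulative eigenvalue share
    reaches ``variance_keep``.  The eigenproblem is solved through the thin
    SVD of the centered matrix, which is exact and avoids forming the
    (feature_dim x feature_dim) covariance when patches are large.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("X must be (feature_dim, n_p) with n_p >= 2")
    if not 0 < variance_keep <= 1:
        raise ValueError("variance_keep must be in (0, 1]")
    n_p = X.shape[1]
    Xc = X - X.mean(axis=1, keepdims=True)
    U, svals, _ = np.linalg.svd(Xc, full_matrices=False)
    eigvals = svals ** 2 / (n_p - 1)
    total = eigvals.sum()
    if total <= 0:
        return PatchFeatureMatrix(X=X, eigvals=eigvals,
                                  basis=np.zeros((X.shape[0], 0)), d=0,
                                  X_reduced=np.zeros((0, n_p)),
                                  degenerate=True)
    cum = np.cumsum(eigvals) / total
    d = int(np.searchsorted(cum, variance_keep - 1e-12) + 1)
    d = min(d, int(np.sum(eigvals > total * 1e-12)))
    basis = U[:, :d]
    return PatchFeatureMatrix(X=X, eigvals=eigvals, basis=basis, d=d,
                              X_reduced=basis.T @ Xc)


def _center_weights(grid: PatchGrid, w_k: float) -> np.ndarray:
    h, w = grid.image_shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    d = np.hypot(grid.centers[:, 1] - cx, grid.centers[:, 0] - cy)
    D = float(np.hypot(cx, cy)) or 1.0
    return 1.0 - w_k * d / D


def patch_saliency(grid: PatchGrid, reduced: PatchFeatureMatrix,
                   L_nb: int | None = None, w_k: float = 0.0,
                   smooth_sigma: float | None = None) -> PatchSaliency:
    """Spatially-weighted patch dissimilarity saliency.

    For each patch i the L1 distances in reduced feature space to its
    neighbours j (all other patches, or the ``L_nb`` nearest by
    patch-center distance) are summed with weights 1/(1 + dist(p_i, p_j)),
    dist normalized by the image diagonal, and scaled by the center weight
    omega(i).  Scores are min-max normalized, painted back onto the patch
    tiling, and Gaussian-smoothed (sigma defaults to t/2).
    """
    if reduced.d == 0:
        smap = SaliencyMap(grid=np.zeros(grid.image_shape), source="model_P",
                           normalization="minmax01", degenerate=True)
        return PatchSaliency(scores=np.zeros(grid.n_p), map=smap, grid=grid,
                             degenerate=True)
    n_p = grid.n_p
    diag = float(np.hypot(*grid.image_shape)) or 1.0
    spatial = squareform(pdist(grid.centers)) / diag
    feat_l1 = cdist(reduced.X_reduced.T, reduced.X_reduced.T,
                    metric="cityblock")
    weights = 1.0 / (1.0 + spatial)
    np.fill_diagonal(weights, 0.0)  # self term is zero anyway (|x-x|=0)
    if L_nb is not None and L_nb < n_p - 1:
        keep = np.zeros_like(weights, dtype=bool)
        order = np.argsort(spatial, axis=1, kind="stable")
        for i in range(n_p):
            neigh = [j for j in order[i] if j != i][:L_nb]
            keep[i, neigh] = True
        weights = np.where(keep, weights, 0.0)
    scores = (feat_l1 * weights).sum(axis=1)
    scores = scores * _center_weights(grid, w_k)

    norm_scores, degenerate = minmax_normalize(scores)
    raster = np.zeros(grid.image_shape)
    t = grid.t
    for idx in range(n_p):
        pr, pc = divmod(idx, grid.n_cols)
        raster[pr * t:(pr + 1) * t, pc * t:(pc + 1) * t] = norm_scores[idx]
    # pixels cropped out of the tiling keep the nearest patch's score
    if grid.n_rows * t < grid.image_shape[0]:
        raster[grid.n_rows * t:, :] = raster[grid.n_rows * t - 1, :]
    if grid.n_cols * t < grid.image_shape[1]:
        raster[:, grid.n_cols * t:] = raster[:, grid.n_cols * t - 1][:, None]
    sigma = smooth_sigma if smooth_sigma is not None else t / 2.0
    if sigma > 0:
        raster = ndimage.gaussian_filter(raster, sigma=sigma, mode="nearest")
    raster, map_degen = minmax_normalize(raster)
    smap = SaliencyMap(grid=raster, source="model_P",
                       normalization="minmax01",
                       degenerate=degenerate or map_degen)
    return PatchSaliency(scores=scores, map=smap, grid=grid,
                         degenerate=degenerate)


def patch_saliency_scores_naive(reduced: np.ndarray, centers: np.ndarray,
                                image_shape: tuple[int, int],
                                w_k: float = 0.0) -> np.ndarray:
    """Reference double-loop evaluation of the per-patch scores (all-patch
    neighbourhood); quadratic and intended for small instances."""
    d, n_p = reduced.shape
    diag = float(np.hypot(*image_shape)) or 1.0
    h, w = image_shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    D = float(np.hypot(cx, cy)) or 1.0
    scores = np.zeros(n_p)
    for i in range(n_p):
        acc = 0.0
        for j in range(n_p):
            if j == i:
                continue
            l1 = float(np.abs(reduced[:, i] - reduced[:, j]).sum())
            dist = float(np.hypot(centers[i, 0] - centers[j, 0],
                                  centers[i, 1] - centers[j, 1])) / diag
            acc += l1 / (1.0 + dist)
        omega = 1.0 - w_k * float(
            np.hypot(centers[i, 1] - cx, centers[i, 0] - cy)) / D
        scores[i] = omega * acc
    return scores


def multiscale_patch_saliency(image: np.ndarray,
                              t_subset: tuple[int, ...] = PATCH_SIZES,
                              w_k: float = 0.0,
                              variance_keep: float = DEFAULT_VARIANCE_KEEP,
                              L_nb: int | None = None,
                              image_id: str = "") -> SaliencyMap:
    """Average the per-size patch saliency maps over a patch-size subset.

    Each size's map is computed at full resolution and min-max normalized;
    the subset average is re-normalized.  ``t_subset`` lists patch sides
    from {64, 32, 16, 8}; the age-adapted subsets are contiguous runs
    a..4 in scale indices (64 = index 1, coarsest).
    """
    if not t_subset:
        raise ValueError("t_subset must be non-empty")
    sigma = min(t_subset) / 2.0  # smoothing set by the finest size used
    maps = []
    for t in t_subset:
        grid, X = extract_patch_features(image, t)
        reduced = pca_reduce(X, variance_keep=variance_keep)
        ps = patch_saliency(grid, reduced, L_nb=L_nb, w_k=w_k,
                            smooth_sigma=sigma)
        maps.append(ps.map.grid)
    mean = np.mean(maps, axis=0)
    grid_out, degenerate = minmax_normalize(mean)
    return SaliencyMap(grid=grid_out, image_id=image_id, source="model_P",
                       normalization="minmax01", degenerate=degenerate)


def scale_indices_to_sizes(start: int) -> tuple[int, ...]:
    """Map an age-adapted scale-subset start a in 1..4 to patch sizes a..4
    (1 = 64 px, 4 = 8 px)."""
    if not 1 <= start <= 4:
        raise ValueError("scale index must be in 1..4")
    return PATCH_SIZES[start - 1:]
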