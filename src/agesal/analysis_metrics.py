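"""Gaze-distribution metrics: explorativeness entropy, thresholded-ROC
agreement, and center bias.

Explorativeness of a cohort on one image is the first-order entropy of its
human saliency map ``U``:

    H(U) = sum_l h(l) * log(L / h(l))

where ``h(l)`` is the count of pixels falling in intensity bin ``l`` and
``L`` the total pixel count.  This equals ``L`` times the Shannon entropy
(nats) of the normalized histogram; a saliency map spread over many
intensity levels (scattered gaze) scores high, a map concentrated in few
levels (clustered gaze) scores low.

Agreement between a source group's saliency map and a target group's
fixations is measured by thresholding the source map at T coverage levels
of its most salient area; each level yields one (FPR, TPR) operating point
over the target fixation pixels, and the trapezoid area under the resulting
ROC curve is the agreement score.  TPR is the fraction of target fixation
pixels inside the thresholded mask.  FPR is implemented as the standard
false-positive *rate* FP / (FP + TN) over non-fixated pixels, which keeps
the abscissa in [0, 1] as an ROC requires.

Center bias of a cohort is read off the *center map* — the average of its
per-image saliency maps: the Euclidean distance from the center map's
intensity centroid to the geometric image center (small distance = strong
bias), plus the AUC of the center map itself used as a predictor.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from agesal.gaze_data import (
    FixationMap,
    FixationTable,
    SaliencyMap,
    build_fixation_map,
    build_human_saliency_map,
    minmax_normalize,
)

logger = logging.getLogger(__name__)


@dataclass
class EntropyResult:
    """Entropy of one saliency map: H in pixel-nats, pixel count L, and the
    occupancy histogram over B intensity bins."""

    H: float
    L: int
    histogram: np.ndarray
    degenerate: bool = False


@dataclass(frozen=True)
class AgreementConfig:
    """Thresholding schedule for the agreement ROC.

    ``coverage_levels`` are fractions of the most-salient image area; they
    must be strictly increasing and end at 1.0.  Default: 20 levels,
    5%, 10%, ..., 100%.
    """

    coverage_levels: tuple[float, ...] = tuple(
        round(0.05 * k, 10) for k in range(1, 21)
    )

    def __post_init__(self) -> None:
        lv = self.coverage_levels
        if len(lv) < 2:
            raise ValueError("need at least two coverage levels")
        if any(b <= a for a, b in zip(lv, lv[1:])):
            raise ValueError("coverage levels must be strictly increasing")
        if not (0 < lv[0] and abs(lv[-1] - 1.0) < 1e-12):
            raise ValueError("coverage levels must lie in (0,1] and end at 1")

    @property
    def T(self) -> int:
        return len(self.coverage_levels)


@dataclass
class RocCurve:
    """ROC operating points (FPR, TPR) including the (0,0) and (1,1)
    anchors, with the trapezoid area under the curve."""

    points: list[tuple[float, float]]
    auc: float


@dataclass
class CenterBiasResult:
    """Averaged ('center') map of a cohort with its intensity centroid and
    the centroid's distance to the geometric image center, in pixels."""

    center_map: SaliencyMap
    centroid: tuple[float, float]
    distance_px: float


def explorativeness_entropy(smap: SaliencyMap, bins: int = 256,
                            base: float = np.e) -> EntropyResult:
    """First-order entropy of a min-max normalized saliency map.

    ``bins`` equal-width bins on [0, 1] (default 256).  A constant map has a
    single occupied bin and H = 0; it is returned with ``degenerate=True``
    rather than raising.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    grid = smap.grid
    if smap.normalization != "minmax01":
        grid, _ = minmax_normalize(grid)
    L = grid.size
    hist, _ = np.histogram(grid, bins=bins, range=(0.0, 1.0))
    nz = hist[hist > 0]
    H = float(np.sum(nz * (np.log(L / nz) / np.log(base))))
    return EntropyResult(H=H, L=L, histogram=hist, degenerate=len(nz) <= 1)


def threshold_saliency_map(smap: SaliencyMap | np.ndarray,
                           coverage: float) -> np.ndarray:
    """Binary mask of the ``ceil(coverage * L)`` most salient pixels.

    Ties at the cut value are broken deterministically in raster order
    (row-major, lowest flat index first).
    """
    if not (0 < coverage <= 1):
        raise ValueError(f"coverage must be in (0, 1], got {coverage}")
    grid = smap.grid if isinstance(smap, SaliencyMap) else np.asarray(smap)
    flat = grid.ravel()
    k = int(np.ceil(coverage * flat.size))
    # stable sort on descending value keeps raster order within ties
    order = np.argsort(-flat, kind="stable")
    mask = np.zeros(flat.size, dtype=bool)
    mask[order[:k]] = True
    return mask.reshape(grid.shape)


def agreement_auc(source_map: SaliencyMap,
                  target_fixations: FixationMap,
                  cfg: AgreementConfig | None = None) -> RocCurve:
    """ROC agreement of a source saliency map with target fixation pixels.

    For each coverage level the source map is thresholded to a binary mask;
    TPR = fixated pixels inside the mask / all fixated pixels, FPR =
    non-fixated pixels inside the mask / all non-fixated pixels.  Points are
    anchored with (0,0) and (1,1) and integrated by the trapezoid rule.
    """
    cfg = cfg or AgreementConfig()
    if source_map.grid.shape != target_fixations.grid.shape:
        raise ValueError(
            f"dims mismatch: map {source_map.grid.shape} vs fixations "
            f"{target_fixations.grid.shape}"
        )
    fix = target_fixations.grid.astype(bool)
    n_pos = int(fix.sum())
    if n_pos == 0:
        raise ValueError("target fixation map has no fixated pixels")
    n_neg = fix.size - n_pos

    flat = source_map.grid.ravel()
    fix_flat = fix.ravel()
    order = np.argsort(-flat, kind="stable")
    # cumulative fixated / non-fixated counts along the salience ranking let
    # all coverage levels be read off one pass
    fix_sorted = fix_flat[order]
    cum_pos = np.cumsum(fix_sorted)
    points = [(0.0, 0.0)]
    for cov in cfg.coverage_levels:
        k = int(np.ceil(cov * flat.size))
        tp = int(cum_pos[k - 1])
        fp = k - tp
        tpr = tp / n_pos
        fpr = fp / n_neg if n_neg else 1.0
        points.append((fpr, tpr))
    points.append((1.0, 1.0))
    pts = sorted(set(points))
    fprs = np.array([p[0] for p in pts])
    tprs = np.array([p[1] for p in pts])
    auc = float(np.trapezoid(tprs, fprs))
    return RocCurve(points=pts, auc=auc)


def agreement_matrix(
    table: FixationTable,
    groups: Sequence[str],
    images: Sequence[str],
    sigma: float | None = None,
    cfg: AgreementConfig | None = None,
) -> pd.DataFrame:
    """Source-by-target table of mean agreement AUC.

    Entry (g_s, g_t) is the mean over images of the AUC of g_s's human
    saliency map predicting the pooled fixation pixels of g_t.  The diagonal
    is the intra-group agreement, off-diagonal entries the inter-group
    agreement.  (group, image) cells without fixations are skipped with a
    warning.
    """
    cfg = cfg or AgreementConfig()
    smaps: dict[tuple[str, str], SaliencyMap] = {}
    fmaps: dict[tuple[str, str], FixationMap] = {}
    for g, im in itertools.product(groups, images):
        try:
            fmap = build_fixation_map(table, g, im)
        except LookupError:
            logger.warning("no fixations for group=%s image=%s; skipped", g, im)
            continue
        fmaps[(g, im)] = fmap
        smaps[(g, im)] = build_human_saliency_map(fmap, sigma=sigma)

    out = pd.DataFrame(index=list(groups), columns=list(groups), dtype=float)
    for gs, gt in itertools.product(groups, groups):
        aucs = [
            agreement_auc(smaps[(gs, im)], fmaps[(gt, im)], cfg).auc
            for im in images
            if (gs, im) in smaps and (gt, im) in fmaps
        ]
        out.loc[gs, gt] = float(np.mean(aucs)) if aucs else np.nan
    out.index.name = "source"
    out.columns.name = "target"
    return out


def compute_center_map(maps: Sequence[SaliencyMap]) -> CenterBiasResult:
    """Average a cohort's saliency maps and locate the centroid.

    The center map is the pixel-wise mean of the input maps, min-max
    normalized.  The centroid is the intensity-weighted center of mass; its
    Euclidean distance to the geometric center ((w-1)/2, (h-1)/2) is the
    center-bias statistic (smaller = more centrally biased cohort).
    """
    if not maps:
        raise ValueError("need at least one saliency map")
    shape = maps[0].grid.shape
    if any(m.grid.shape != shape for m in maps):
        raise ValueError("all maps must share dimensions")
    mean = np.mean([m.grid for m in maps], axis=0)
    grid, degenerate = minmax_normalize(mean)
    h, w = shape
    if degenerate or grid.sum() == 0:
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    else:
        cy, cx = ndimage.center_of_mass(grid)
    dist = float(np.hypot(cx - (w - 1) / 2.0, cy - (h - 1) / 2.0))
    cmap = SaliencyMap(grid=grid, source="center_map",
                       normalization="minmax01", degenerate=degenerate)
    return CenterBiasResult(center_map=cmap, centroid=(float(cx), float(cy)),
                            distance_px=dist)


def center_map_prediction_auc(cbr: CenterBiasResult,
                              target_fixations: FixationMap,
                              cfg: AgreementConfig | None = None) -> float:
    """AUC of the center map used as a saliency predictor for a target
    group's fixations."""
    return agreement_auc(cbr.center_map, target_fixations, cfg).auc
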