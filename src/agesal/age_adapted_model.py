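"""Age-specific learned feature combination, center bias, and scale-subset
selection.

A cohort's model has four parameters: a scale-subset start ``s`` (which
levels of detail enter the conspicuity maps), a weight vector ``w_g`` and
bias ``b_g`` combining the per-pixel intensity/color/orientation conspicuity
features ("S+I+C": score = w_g . X + b_g, learned by a linear max-margin
classifier on strongly salient vs strongly non-salient pixels of the
cohort's own human saliency maps), and a center-bias strength ``w_k`` in
[0, 1] blending the map with the center weight C(i) = 1 - d/D, which falls
linearly from 1 at the image center to 0 at the farthest corner:
out = (1 - w_k) * map + w_k * C.  The convex blend is the form under which
``w_k`` is identifiable from data: at full strength it ranks purely by
centrality, so over-centering a weakly-biased cohort costs AUC and the
1-D fit lands at an interior optimum that tracks the cohort's true
central tendency.

``scan_scale_subsets`` evaluates a cohort over all six subset starts and
reports the AUC-optimal one — the procedure that ties a cohort's preferred
level of detail to its explorativeness (less-explorative cohorts are best
fit by coarser-only subsets).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.svm import LinearSVC

from agesal.analysis_metrics import AgreementConfig, agreement_auc
from agesal.gaze_data import (
    FixationTable,
    SaliencyMap,
    build_fixation_map,
    build_human_saliency_map,
    default_sigma,
    minmax_normalize,
)
from agesal.itti_saliency import ConspicuityStack

logger = logging.getLogger(__name__)

FEATURE_NAMES = ("intensity", "color", "orientation")
DEFAULT_P = 10

#: default center-bias strengths for the built-in group profiles, youngest
#: (strongest central tendency) to adult; all overridable and fittable.
DEFAULT_WK = {"4y": 0.6, "6y": 0.5, "8y": 0.35, "adult": 0.3}


@dataclass
class TrainingSamples:
    """P strongly salient and P strongly non-salient pixel locations drawn
    from a cohort's human saliency map, as (row, col) pairs."""

    positives: list[tuple[int, int]]
    negatives: list[tuple[int, int]]
    P: int
    source: str = ""


@dataclass
class GroupModel:
    """Learned saliency parameters for one age group."""

    group: str
    w_g: np.ndarray
    b_g: float
    s: int
    w_k: float = 0.0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "group": self.group,
            "w_g": [float(v) for v in self.w_g],
            "b_g": float(self.b_g),
            "s": int(self.s),
            "w_k": float(self.w_k),
        }, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroupModel":
        d = json.loads(Path(path).read_text())
        return cls(group=d["group"], w_g=np.asarray(d["w_g"], dtype=float),
                   b_g=float(d["b_g"]), s=int(d["s"]), w_k=float(d["w_k"]))


@dataclass
class CenterWeightMap:
    """Per-pixel center weight C(i) = 1 - d(c, p_i)/D with D the
    center-to-farthest-corner distance."""

    grid: np.ndarray
    D: float


def center_weight_map(dims: tuple[int, int]) -> CenterWeightMap:
    """Linear center weighting for an (height, width) raster.

    C equals 1 at the geometric center ((w-1)/2, (h-1)/2) and 0 at the
    farthest corner.
    """
    h, w = dims
    if h < 1 or w < 1:
        raise ValueError("dims must be at least 1x1")
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    d = np.hypot(xx - cx, yy - cy)
    D = float(d.max()) if d.max() > 0 else 1.0
    return CenterWeightMap(grid=1.0 - d / D, D=D)


def apply_center_bias(smap: SaliencyMap, w_k: float) -> SaliencyMap:
    """Blend a saliency map with the age-weighted center factor.

    out(i) = (1 - w_k) * map(i) + w_k * C(i), then min-max re-normalized
    (the input is brought to [0, 1] first so the two terms are on the same
    scale).  w_k = 0 is the identity; w_k = 1 scores purely by centrality,
    zeroing the farthest corners regardless of features.
    """
    if not 0.0 <= w_k <= 1.0:
        raise ValueError(f"w_k must be in [0, 1], got {w_k}")
    if w_k == 0.0:
        return smap
    base = smap.grid
    if smap.normalization != "minmax01":
        base, _ = minmax_normalize(base)
    C = center_weight_map(smap.grid.shape).grid
    grid = (1.0 - w_k) * base + w_k * C
    grid, degenerate = minmax_normalize(grid)
    return SaliencyMap(grid=grid, image_id=smap.image_id, source=smap.source,
                       normalization="minmax01", degenerate=degenerate)


def select_training_samples(human_map: SaliencyMap, P: int = DEFAULT_P,
                            min_sep: float | None = None) -> TrainingSamples:
    """Pick P most-salient (positive) and P least-salient (negative) pixels.

    Greedy selection in value order with a pairwise separation constraint
    of ``min_sep`` pixels (default: the smoothing sigma for the map width)
    so the positives do not all collapse onto adjacent pixels of a single
    peak.  Ties are broken by raster order.  If the constraint cannot be
    met, it is halved with a warning until P samples fit.
    """
    if P < 1:
        raise ValueError("P must be >= 1")
    grid = human_map.grid
    if grid.max() - grid.min() <= 0:
        raise ValueError("cannot sample a constant (degenerate) map")
    if min_sep is None:
        min_sep = default_sigma(grid.shape[1])

    flat = grid.ravel()
    desc = np.argsort(-flat, kind="stable")

    def greedy(order: np.ndarray, sep: float) -> list[tuple[int, int]]:
        picked: list[tuple[int, int]] = []
        for fi in order:
            r, c = divmod(int(fi), grid.shape[1])
            if all((r - pr) ** 2 + (c - pc) ** 2 >= sep ** 2
                   for pr, pc in picked):
                picked.append((r, c))
                if len(picked) == P:
                    break
        return picked

    sep = float(min_sep)
    pos = greedy(desc, sep)
    neg = greedy(desc[::-1], sep)
    while (len(pos) < P or len(neg) < P) and sep > 0.5:
        sep /= 2.0
        logger.warning("min_sep relaxed to %.2f px to fit %d samples",
                       sep, P)
        pos = greedy(desc, sep)
        neg = greedy(desc[::-1], sep)
    if set(pos) & set(neg):
        raise ValueError("positive and negative samples overlap; "
                         "map has too little dynamic range")
    return TrainingSamples(positives=pos, negatives=neg, P=P)


def _stack_for(image: np.ndarray | ConspicuityStack) -> ConspicuityStack:
    if isinstance(image, ConspicuityStack):
        return image
    return ConspicuityStack.from_image(image)


def train_group_model(
    images: Mapping[str, np.ndarray | ConspicuityStack],
    gaze: FixationTable,
    group: str,
    s: int = 1,
    P: int = DEFAULT_P,
    sigma: float | None = None,
    w_k: float | None = None,
    fit_w_k: bool = False,
    C: float = 1.0,
) -> GroupModel:
    """Learn the per-group feature-combination weights (w_g, b_g).

    For every training image the per-pixel (intensity, color, orientation)
    conspicuity features at subset start ``s`` are sampled at P positive
    and P negative locations of the group's human saliency map, and a
    linear max-margin classifier (L2-regularized hinge loss, liblinear)
    is fit on the pooled samples.  ``w_k`` is taken from the per-group
    defaults unless given; with ``fit_w_k=True`` it is instead chosen by a
    1-D grid search maximizing the training-set agreement AUC.

    ``images`` maps image_id to an RGB array or a prebuilt
    :class:`ConspicuityStack` (reuse stacks when scanning several s).
    """
    if len(images) < 2:
        raise ValueError("need at least 2 training images")
    X_rows: list[np.ndarray] = []
    y_rows: list[int] = []
    stacks: dict[str, ConspicuityStack] = {}
    for image_id, img in images.items():
        stack = _stack_for(img)
        stacks[image_id] = stack
        fmap = build_fixation_map(gaze, group, image_id)
        smap = build_human_saliency_map(fmap, sigma=sigma)
        samples = select_training_samples(smap, P=P)
        feats = stack.feature_images(s)
        for r, c in samples.positives:
            X_rows.append(feats[r, c])
            y_rows.append(1)
        for r, c in samples.negatives:
            X_rows.append(feats[r, c])
            y_rows.append(0)
    X = np.asarray(X_rows)
    y = np.asarray(y_rows)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels are all one class")
    clf = LinearSVC(C=C, loss="hinge", max_iter=20000, random_state=0)
    clf.fit(X, y)
    model = GroupModel(group=group, w_g=clf.coef_.ravel().copy(),
                       b_g=float(clf.intercept_[0]), s=s,
                       w_k=0.0)
    if fit_w_k:
        model.w_k = _fit_center_strength(model, stacks, gaze, group)
    elif w_k is not None:
        model.w_k = float(w_k)
    else:
        model.w_k = DEFAULT_WK.get(group, 0.0)
    return model


def _fit_center_strength(model: GroupModel,
                         stacks: Mapping[str, ConspicuityStack],
                         gaze: FixationTable, group: str,
                         grid: Sequence[float] | None = None,
                         cfg: AgreementConfig | None = None) -> float:
    """1-D grid search over w_k maximizing the training agreement AUC."""
    grid = list(grid) if grid is not None else [round(0.1 * k, 10)
                                               for k in range(11)]
    base_maps = {
        image_id: predict_saliency_SIC(stack, model, apply_bias=False)
        for image_id, stack in stacks.items()
    }
    fmaps = {
        image_id: build_fixation_map(gaze, group, image_id)
        for image_id in stacks
    }
    best_wk, best_auc = 0.0, -np.inf
    for wk in grid:
        aucs = [
            agreement_auc(apply_center_bias(base_maps[i], wk), fmaps[i],
                          cfg).auc
            for i in stacks
        ]
        mean = float(np.mean(aucs))
        if mean > best_auc:
            best_wk, best_auc = float(wk), mean
    return best_wk


def predict_saliency_SIC(image: np.ndarray | ConspicuityStack,
                         model: GroupModel, image_id: str = "",
                         apply_bias: bool = True) -> SaliencyMap:
    """Saliency map from the learned combination: score = w_g . X + b_g
    per pixel, min-max normalized, then center-bias modulated by the
    model's w_k."""
    stack = _stack_for(image)
    feats = stack.feature_images(model.s)
    if feats.shape[-1] != model.w_g.shape[0]:
        raise ValueError(
            f"feature dim {feats.shape[-1]} != weight dim "
            f"{model.w_g.shape[0]}")
    score = feats @ model.w_g + model.b_g
    grid, degenerate = minmax_normalize(score)
    smap = SaliencyMap(grid=grid, image_id=image_id, source="model_SIC",
                       normalization="minmax01", degenerate=degenerate)
    if apply_bias and model.w_k:
        smap = apply_center_bias(smap, model.w_k)
        smap.source = "model_SIC"
    return smap


def scan_scale_subsets(
    images: Mapping[str, np.ndarray | ConspicuityStack],
    gaze: FixationTable,
    group: str,
    s_values: Sequence[int] = (1, 2, 3, 4, 5, 6),
    w_k: float = 0.0,
    cfg: AgreementConfig | None = None,
) -> pd.DataFrame:
    """Mean agreement AUC of the "S" model per scale-subset start.

    For each ``s`` the model map of every evaluation image is scored
    against the group's pooled fixations; the table has one row per s with
    the mean AUC, and ``attrs['s_star']`` holds the argmax (first one on
    ties).
    """
    stacks = {iid: _stack_for(img) for iid, img in images.items()}
    fmaps = {iid: build_fixation_map(gaze, group, iid) for iid in stacks}
    rows = []
    for s in s_values:
        aucs = [
            agreement_auc(stacks[iid].saliency(s, w_k=w_k), fmaps[iid],
                          cfg).auc
            for iid in stacks
        ]
        rows.append({"s": int(s), "mean_auc": float(np.mean(aucs)),
                     "n_images": len(aucs)})
    out = pd.DataFrame(rows)
    out.attrs["s_star"] = int(out.loc[out["mean_auc"].idxmax(), "s"])
    return out
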