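"""Seeded synthetic stimuli and observer cohorts.

The study conditions this simulator emulates: several observer groups
free-view a shared set of scenes; groups differ in how widely they spread
their gaze (explorativeness), in which regions they prefer, and in how
strongly their fixations cluster at the screen center.  Each group is a
:class:`GroupProfile` with three generative knobs:

``tau``
    exploration temperature.  Fixations are sampled from the attention
    density raised to 1/tau: low tau concentrates fixations on the
    density's peaks (a less-explorative, child-like cohort), high tau
    flattens the density (explorative, adult-like).
``lambda_cb``
    weight of a central-Gaussian mixture component — the center-bias knob.
``source_mode``
    where the attention density comes from: the bottom-up conspicuity of
    the stimulus restricted to coarse scales (``coarse_conspicuity`` with a
    true subset start), all scales (``full_conspicuity``), an explicit map,
    or uniform.

Fixations are i.i.d. per observer — the analyses consume only fixation
locations, so saccade dynamics are deliberately not modelled.  Everything
is bit-identically regenerable from (profiles, stimuli, seed).

Also provided: pop-out arrays (a single bar differing in color or
orientation — the canonical bottom-up saliency probe) and layered scenes
mixing large low-frequency blobs with small high-contrast details, used to
separate coarse-scale from fine-scale attention.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from agesal.gaze_data import FixationRecord, FixationTable

logger = logging.getLogger(__name__)

DEFAULT_N_OBSERVERS = 20
DEFAULT_FIXATIONS_PER_OBSERVER = 30
CENTER_SIGMA_FRACTION = 1 / 6  # central-Gaussian sigma = width/6


@dataclass
class GroupProfile:
    """Generative description of one simulated observer group."""

    label: str
    n_observers: int = DEFAULT_N_OBSERVERS
    fixations_per_observer: int = DEFAULT_FIXATIONS_PER_OBSERVER
    lambda_cb: float = 0.3
    tau: float = 1.0
    source_mode: str = "full_conspicuity"  # or coarse_conspicuity,
    # explicit_map, uniform
    s_true: int = 5  # subset start used by coarse_conspicuity
    region_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lambda_cb <= 1.0:
            raise ValueError("lambda_cb must be in [0, 1]")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        modes = {"coarse_conspicuity", "full_conspicuity", "explicit_map",
                 "uniform"}
        if self.source_mode not in modes:
            raise ValueError(f"source_mode must be one of {sorted(modes)}")


@dataclass
class SimulatedCohort:
    """A simulated group's fixation table plus its generating densities."""

    table: FixationTable
    truth: dict[str, np.ndarray] = field(default_factory=dict)
    seed: int = 0


def _rng_for(seed: int, *tokens: str) -> np.random.Generator:
    """Independent, reproducible stream keyed by seed and string tokens."""
    keys = [zlib.crc32(t.encode()) for t in tokens]
    return np.random.default_rng(np.random.SeedSequence([seed, *keys]))


def center_gaussian(dims: tuple[int, int],
                    sigma: float | None = None) -> np.ndarray:
    """Central 2-D Gaussian density (sums to 1); sigma defaults to
    width/6."""
    h, w = dims
    if sigma is None:
        sigma = w * CENTER_SIGMA_FRACTION
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    g = np.exp(-(((xx - (w - 1) / 2) ** 2) + ((yy - (h - 1) / 2) ** 2))
               / (2 * sigma ** 2))
    return g / g.sum()


def make_popout_image(dims: tuple[int, int] = (256, 256), n: int = 5,
                      odd_feature: str = "color", seed: int = 0
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Regular n x n array of bars with exactly one odd item.

    ``odd_feature='color'``: green vertical bars, one saturated red (the
    distractor green is muted so the singleton is the unique strong
    chromatic contrast, as in a psychophysical color-singleton display).
    ``odd_feature='orientation'``: light vertical bars, one horizontal.
    Item positions carry +/-2 px jitter and the rendered display is
    antialiased with a 1 px Gaussian.
    Returns (RGB image in [0,1], boolean mask of the odd item's cell).
    """
    if n < 3:
        raise ValueError("need at least a 3x3 item grid")
    if odd_feature not in {"color", "orientation"}:
        raise ValueError("odd_feature must be 'color' or 'orientation'")
    h, w = dims
    rng = _rng_for(seed, "popout", odd_feature)
    img = np.full((h, w, 3), 0.08)
    cell_h, cell_w = h // n, w // n
    odd = int(rng.integers(0, n * n))
    bar_h = max(3, int(cell_h * 0.55))
    bar_w = max(2, int(cell_w * 0.14))
    mask = np.zeros((h, w), dtype=bool)
    for k in range(n * n):
        gr, gc = divmod(k, n)
        cy = gr * cell_h + cell_h // 2 + int(rng.integers(-2, 3))
        cx = gc * cell_w + cell_w // 2 + int(rng.integers(-2, 3))
        horizontal = odd_feature == "orientation" and k == odd
        bh, bw = (bar_w, bar_h) if horizontal else (bar_h, bar_w)
        y0, y1 = max(0, cy - bh // 2), min(h, cy + (bh + 1) // 2)
        x0, x1 = max(0, cx - bw // 2), min(w, cx + (bw + 1) // 2)
        if odd_feature == "color":
            color = (0.85, 0.06, 0.06) if k == odd else (0.33, 0.45, 0.33)
        else:
            color = (0.85, 0.85, 0.85)
        img[y0:y1, x0:x1] = color
        if k == odd:
            mask[gr * cell_h:(gr + 1) * cell_h,
                 gc * cell_w:(gc + 1) * cell_w] = True
    from scipy import ndimage
    return ndimage.gaussian_filter(img, sigma=(1.0, 1.0, 0)), mask


def make_layered_scene(dims: tuple[int, int] = (256, 256),
                       n_coarse_blobs: int = 3, n_fine_details: int = 8,
                       seed: int = 0
                       ) -> tuple[np.ndarray, list[tuple[int, int]],
                                  list[tuple[int, int]]]:
    """Scene mixing large low-frequency blobs with small sharp details.

    Blobs are broad colored Gaussians (coarse structure); details are small
    high-contrast crosses (fine structure).  Placements are rejection-
    sampled to be pairwise disjoint; if 100 attempts fail the remaining
    count is dropped with a warning.  Returns (RGB image, blob centers,
    detail centers) with centers as (row, col).
    """
    if n_coarse_blobs < 1 or n_fine_details < 1:
        raise ValueError("counts must be >= 1")
    h, w = dims
    rng = _rng_for(seed, "layered")
    img = np.full((h, w, 3), 0.45)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)

    blob_sigma = min(h, w) / 10.0
    min_sep = 2.2 * blob_sigma
    coarse: list[tuple[int, int]] = []
    attempts = 0
    while len(coarse) < n_coarse_blobs and attempts < 100 * n_coarse_blobs:
        attempts += 1
        r = int(rng.integers(int(blob_sigma), h - int(blob_sigma)))
        c = int(rng.integers(int(blob_sigma), w - int(blob_sigma)))
        if all(np.hypot(r - pr, c - pc) >= min_sep for pr, pc in coarse):
            coarse.append((r, c))
    if len(coarse) < n_coarse_blobs:
        logger.warning("placed only %d/%d coarse blobs", len(coarse),
                       n_coarse_blobs)
    for r, c in coarse:
        g = np.exp(-((xx - c) ** 2 + (yy - r) ** 2) / (2 * blob_sigma ** 2))
        tint = rng.uniform(-0.35, 0.35, size=3)
        img += g[..., None] * tint

    detail_half = 3
    fine_sep = 4 * detail_half  # details only need to clear each other
    blob_clear = 1.2 * blob_sigma
    fine: list[tuple[int, int]] = []
    attempts = 0
    while len(fine) < n_fine_details and attempts < 100 * n_fine_details:
        attempts += 1
        r = int(rng.integers(detail_half + 2, h - detail_half - 2))
        c = int(rng.integers(detail_half + 2, w - detail_half - 2))
        if all(np.hypot(r - pr, c - pc) >= blob_clear
               for pr, pc in coarse) and \
           all(np.hypot(r - pr, c - pc) >= fine_sep for pr, pc in fine):
            fine.append((r, c))
    if len(fine) < n_fine_details:
        logger.warning("placed only %d/%d fine details", len(fine),
                       n_fine_details)
    for r, c in fine:
        val = 1.0 if rng.random() < 0.5 else 0.0
        img[r - detail_half:r + detail_half + 1, c - 1:c + 2] = val
        img[r - 1:r + 2, c - detail_half:c + detail_half + 1] = val
    return np.clip(img, 0, 1), coarse, fine


def attention_density(image: np.ndarray, profile: GroupProfile,
                      explicit: np.ndarray | None = None) -> np.ndarray:
    """Resolve a profile's raw attention map for one stimulus (unnormalized,
    before the central mixture and temperature are applied)."""
    if profile.source_mode == "uniform":
        return np.ones(image.shape[:2])
    if profile.source_mode == "explicit_map":
        if explicit is None:
            raise ValueError("explicit_map profile needs an attention map")
        if explicit.shape != image.shape[:2]:
            raise ValueError("explicit map dims must match the stimulus")
        return np.asarray(explicit, dtype=float)
    from agesal.itti_saliency import saliency_S
    s = profile.s_true if profile.source_mode == "coarse_conspicuity" else 1
    return saliency_S(image, s=s).grid


def mixture_density(attention: np.ndarray, lambda_cb: float,
                    tau: float) -> np.ndarray:
    """Sampling density: [(1-lambda)*A + lambda*G_center]^(1/tau),
    normalized to sum 1."""
    a_sum = attention.sum()
    if lambda_cb < 1.0 and a_sum <= 0:
        raise ValueError("attention map is all zero")
    a_norm = attention / a_sum if a_sum > 0 else attention
    g = center_gaussian(attention.shape)
    mix = (1.0 - lambda_cb) * a_norm + lambda_cb * g
    if mix.sum() <= 0:
        raise ValueError("sampling density is all zero")
    dens = mix ** (1.0 / tau)
    return dens / dens.sum()


def simulate_group_fixations(
    stimuli: Mapping[str, np.ndarray],
    profile: GroupProfile,
    seed: int = 0,
    attention_maps: Mapping[str, np.ndarray] | None = None,
) -> SimulatedCohort:
    """Sample a full simulated cohort for one group profile.

    Per stimulus the attention density is resolved from the profile's
    source mode, mixed with the central Gaussian (weight ``lambda_cb``),
    exponentiated by 1/tau and renormalized; each of ``n_observers``
    observers then draws ``fixations_per_observer`` i.i.d. pixel locations.
    The per-image sampling densities are kept in ``truth``.
    """
    records: list[FixationRecord] = []
    image_dims: dict[str, tuple[int, int]] = {}
    truth: dict[str, np.ndarray] = {}
    for image_id, image in stimuli.items():
        explicit = (attention_maps or {}).get(image_id)
        attn = attention_density(image, profile, explicit=explicit)
        dens = mixture_density(attn, profile.lambda_cb, profile.tau)
        truth[image_id] = dens
        h, w = dens.shape
        image_dims[image_id] = (w, h)
        flat = dens.ravel()
        for ob in range(profile.n_observers):
            rng = _rng_for(seed, profile.label, image_id, f"ob{ob}")
            picks = rng.choice(flat.size, size=profile.fixations_per_observer,
                               p=flat)
            rows, cols = np.divmod(picks, w)
            for k, (r, c) in enumerate(zip(rows, cols)):
                records.append(FixationRecord(
                    observer_id=f"{profile.label}_ob{ob:02d}",
                    group=profile.label, image_id=image_id,
                    x=float(c), y=float(r), index=k,
                ))
    table = FixationTable(records=records, image_dims=image_dims)
    return SimulatedCohort(table=table, truth=truth, seed=seed)


def default_profiles() -> list[GroupProfile]:
    """The built-in four-group cohort, youngest to adult.

    The youngest profile is the least explorative (low tau) with the
    strongest center bias (high lambda_cb); explorativeness rises and
    center bias falls toward the adult profile, matching the developmental
    orderings the analysis metrics are designed to detect.  Temperatures
    stay below 1 so every cohort remains structure-driven: at higher
    temperatures the sampling density degenerates toward uniform, which no
    free-viewing cohort exhibits and which would confound the spread and
    centrality measures.
    """
    return [
        GroupProfile(label="4y", tau=0.35, lambda_cb=0.55,
                     source_mode="full_conspicuity"),
        GroupProfile(label="6y", tau=0.5, lambda_cb=0.45,
                     source_mode="full_conspicuity"),
        GroupProfile(label="8y", tau=0.7, lambda_cb=0.32,
                     source_mode="full_conspicuity"),
        GroupProfile(label="adult", tau=0.85, lambda_cb=0.25,
                     source_mode="full_conspicuity"),
    ]


def profiles_from_yaml(path) -> list[GroupProfile]:
    """Load group profiles from a YAML list of GroupProfile field maps."""
    import yaml
    data = yaml.safe_load(open(path))
    if not isinstance(data, list):
        raise ValueError("profiles YAML must be a list of mappings")
    return [GroupProfile(**entry) for entry in data]
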