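"""Multi-scale center-surround saliency with age-adapted scale subsets.

The classic bottom-up architecture: a 9-level dyadic Gaussian pyramid is
built for intensity, four broadly-tuned color channels (R, G, B, Y) and
Gabor orientation energy at 0/45/90/135 degrees.  Center-surround feature
maps are differences between a fine "center" level c in {2, 3, 4} and a
coarse "surround" level c + delta, delta in {3, 4}, giving six maps per
feature channel ordered from finest (i = 1, pair (2,3)) to coarsest
(i = 6, pair (4,4)).  Maps pass through the nonlinear normalization N —
which promotes maps with one dominant peak and suppresses maps with many
comparable peaks — and are combined across scales i = s..6 into intensity,
color and orientation conspicuity maps.  The start index ``s`` is the
age-adaptation knob: s = 1 uses all levels of detail (explorative,
adult-like cohorts), s near 6 keeps only the coarsest structure
(less-explorative cohorts).  The final map "S" is the equal-weight mean of
the three normalized conspicuity channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from agesal.gaze_data import SaliencyMap, minmax_normalize

N_LEVELS = 9
CENTER_LEVELS = (2, 3, 4)
SURROUND_DELTAS = (3, 4)
#: (center, delta) pairs in finest-to-coarsest order, indices i = 1..6
SCALE_PAIRS = ((2, 3), (2, 4), (3, 3), (3, 4), (4, 3), (4, 4))
COMMON_LEVEL = 4
ORIENTATIONS = (0.0, 45.0, 90.0, 135.0)
GABOR_FREQUENCY = 0.25  # cycles/pixel at every pyramid level
LOCAL_MAX_THRESHOLD = 0.05
MIN_SHORT_SIDE = 256


def _downsample(a: np.ndarray) -> np.ndarray:
    """One dyadic pyramid step: Gaussian smooth then decimate by 2."""
    return ndimage.gaussian_filter(a, sigma=1.0, mode="nearest")[::2, ::2]


def _pyramid(a: np.ndarray, levels: int = N_LEVELS) -> list[np.ndarray]:
    out = [np.asarray(a, dtype=float)]
    for _ in range(levels - 1):
        out.append(_downsample(out[-1]))
    return out


def _resize_to(a: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    if a.shape == shape:
        return a
    return resize(a, shape, order=1, mode="edge", anti_aliasing=False,
                  preserve_range=True)


@lru_cache(maxsize=64)
def _gabor_kernels(theta_deg: float, frequency: float
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Even/odd Gabor quadrature pair tuned to edges of orientation
    ``theta_deg`` (0 = horizontal edge, 90 = vertical edge/bar)."""
    sigma = 0.56 / frequency
    half = int(np.ceil(3 * sigma))
    y, x = np.mgrid[-half:half + 1, -half:half + 1].astype(float)
    # carrier runs perpendicular to the bar orientation: a theta=90
    # (vertical) bar varies along x, so its carrier is u = x
    t = np.deg2rad(theta_deg)
    u = x * np.sin(t) - y * np.cos(t)
    v = x * np.cos(t) + y * np.sin(t)
    envelope = np.exp(-(u ** 2 + v ** 2) / (2 * sigma ** 2))
    even = envelope * np.cos(2 * np.pi * frequency * u)
    odd = envelope * np.sin(2 * np.pi * frequency * u)
    even -= even.mean()  # zero DC so flat regions give no response
    return even, odd


def _gabor_energy(a: np.ndarray, theta_deg: float,
                  frequency: float = GABOR_FREQUENCY) -> np.ndarray:
    even, odd = _gabor_kernels(theta_deg, frequency)
    re = ndimage.convolve(a, even, mode="nearest")
    im = ndimage.convolve(a, odd, mode="nearest")
    return np.hypot(re, im)


@dataclass
class FeaturePyramids:
    """9-level dyadic pyramids of the early visual feature channels."""

    intensity: list[np.ndarray]
    R: list[np.ndarray]
    G: list[np.ndarray]
    B: list[np.ndarray]
    Y: list[np.ndarray]
    orientation: dict[float, list[np.ndarray]]
    image_shape: tuple[int, int]


def _as_rgb_float(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        image = np.stack([image] * 3, axis=-1)
    if image.ndim != 3 or image.shape[2] < 3:
        raise ValueError(f"expected RGB image, got shape {image.shape}")
    image = image[..., :3]
    if image.max() > 1.0:
        image = image / 255.0
    return image


def build_pyramids(image: np.ndarray) -> FeaturePyramids:
    """Decompose an RGB image into multi-scale feature channels.

    Intensity is (r+g+b)/3.  Color channels follow the broadly-tuned
    opponent construction: r, g, b are first normalized by intensity where
    intensity exceeds 10% of its image maximum (hue decouples from
    luminance; dark pixels are zeroed), then
    R = r-(g+b)/2, G = g-(r+b)/2, B = b-(r+g)/2, Y = (r+g)/2-|r-g|/2-b,
    each rectified at zero.  Orientation channels are quadrature Gabor
    energy of the intensity pyramid at 0/45/90/135 degrees.

    Images with a short side below 256 px are upscaled so the coarsest
    pyramid level stays non-degenerate.
    """
    rgb = _as_rgb_float(image)
    h, w = rgb.shape[:2]
    short = min(h, w)
    if short < MIN_SHORT_SIDE:
        scale = MIN_SHORT_SIDE / short
        new_shape = (int(round(h * scale)), int(round(w * scale)))
        import logging
        logging.getLogger(__name__).warning(
            "image %dx%d below %d px short side; upscaled to %s",
            w, h, MIN_SHORT_SIDE, new_shape[::-1])
        rgb = resize(rgb, new_shape + (3,), order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)

    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    intensity = (r + g + b) / 3.0
    imax = intensity.max()
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = np.where(intensity > 0.1 * imax, intensity, np.inf)
        rn, gn, bn = r / norm, g / norm, b / norm
    R = np.clip(rn - (gn + bn) / 2.0, 0, None)
    G = np.clip(gn - (rn + bn) / 2.0, 0, None)
    B = np.clip(bn - (rn + gn) / 2.0, 0, None)
    Y = np.clip((rn + gn) / 2.0 - np.abs(rn - gn) / 2.0 - bn, 0, None)

    ipyr = _pyramid(intensity)
    orientation = {
        th: [_gabor_energy(lvl, th) for lvl in ipyr] for th in ORIENTATIONS
    }
    return FeaturePyramids(
        intensity=ipyr,
        R=_pyramid(R), G=_pyramid(G), B=_pyramid(B), Y=_pyramid(Y),
        orientation=orientation,
        image_shape=rgb.shape[:2],
    )


def _attenuate_borders(a: np.ndarray, fraction: float = 0.1) -> np.ndarray:
    """Linearly ramp map borders to zero so image-edge convolution
    artifacts cannot masquerade as unique peaks under N."""
    h, w = a.shape
    size = max(1, int(round(min(h, w) * fraction)))
    ramp = np.ones(max(h, w))
    for k in range(size):
        ramp[k] = (k + 1) / (size + 1)
    out = a * ramp[:h, None] * ramp[:h][::-1, None]
    return out * ramp[:w][None, :] * ramp[:w][None, ::-1]


def _center_surround(fine: np.ndarray, coarse: np.ndarray) -> np.ndarray:
    return _attenuate_borders(np.abs(fine - _resize_to(coarse, fine.shape)))


def center_surround_maps(pyr: FeaturePyramids) -> dict:
    """Six center-surround feature maps per channel.

    Returns a dict with keys ``intensity``, ``RG``, ``BY`` (lists of six
    maps each, index 0 = finest scale pair) and ``orientation`` (dict
    theta -> list of six maps).  Color maps use the double-opponent form
    |(R(c)-G(c)) - interp(G(s)-R(s))| and likewise for B/Y.
    """
    out: dict = {"intensity": [], "RG": [], "BY": [], "orientation":
                 {th: [] for th in ORIENTATIONS}}
    for c, delta in SCALE_PAIRS:
        s = c + delta
        out["intensity"].append(
            _center_surround(pyr.intensity[c], pyr.intensity[s]))
        rg_c = pyr.R[c] - pyr.G[c]
        gr_s = pyr.G[s] - pyr.R[s]
        out["RG"].append(_attenuate_borders(
            np.abs(rg_c - _resize_to(gr_s, rg_c.shape))))
        by_c = pyr.B[c] - pyr.Y[c]
        yb_s = pyr.Y[s] - pyr.B[s]
        out["BY"].append(_attenuate_borders(
            np.abs(by_c - _resize_to(yb_s, by_c.shape))))
        for th in ORIENTATIONS:
            out["orientation"][th].append(
                _center_surround(pyr.orientation[th][c],
                                 pyr.orientation[th][s]))
    return out


def normalize_N(feature_map: np.ndarray,
                local_max_threshold: float = LOCAL_MAX_THRESHOLD
                ) -> np.ndarray:
    """Peak-promotion normalization operator N.

    The map is scaled to [0, 1] and multiplied by ``(M - mbar)**2`` where M
    is the global maximum (1 after scaling) and ``mbar`` the mean of all
    *other* local maxima (3x3 neighborhood, above ``local_max_threshold``).
    A map with one dominant peak keeps its weight (factor -> M^2); a map
    with many comparable peaks is suppressed (factor -> 0).  A constant map
    returns zeros.
    """
    feature_map = np.asarray(feature_map, dtype=float)
    # a numerically-silent channel (range at float-noise level) must not be
    # amplified to full scale by the min-max step
    if feature_map.max() - feature_map.min() < 1e-9:
        return np.zeros_like(feature_map)
    scaled, degenerate = minmax_normalize(feature_map)
    if degenerate:
        return scaled
    is_peak = (ndimage.maximum_filter(scaled, size=3, mode="nearest")
               == scaled) & (scaled > local_max_threshold)
    peak_vals = np.sort(scaled[is_peak])[::-1]
    M = 1.0
    if peak_vals.size <= 1:
        factor = M * M
    else:
        others = peak_vals[1:]  # drop one instance of the global max
        mbar = float(others.mean())
        factor = (M - mbar) ** 2
    return scaled * factor


def conspicuity(cs_maps: dict, s: int) -> tuple[np.ndarray, np.ndarray,
                                                np.ndarray]:
    """Across-scale combination of normalized feature maps i = s..6.

    Each map is normalized with N, resized to the common (pyramid level 4)
    raster and summed pixel-wise:

        Ibar = (+)_{i=s..6} N(I_i)
        Cbar = (+)_{i=s..6} [N(RG_i) + N(BY_i)]
        Obar = sum_theta (+)_{i=s..6} N(O_i(theta))
    """
    if not 1 <= s <= 6:
        raise ValueError(f"scale-subset start s must be in 1..6, got {s}")
    shape = cs_maps["intensity"][SCALE_PAIRS.index((4, 3))].shape
    idx = range(s - 1, 6)
    ibar = np.zeros(shape)
    cbar = np.zeros(shape)
    for i in idx:
        ibar += _resize_to(normalize_N(cs_maps["intensity"][i]), shape)
        cbar += _resize_to(normalize_N(cs_maps["RG"][i]), shape)
        cbar += _resize_to(normalize_N(cs_maps["BY"][i]), shape)
    obar = np.zeros(shape)
    for th in ORIENTATIONS:
        acc = np.zeros(shape)
        for i in idx:
            acc += _resize_to(normalize_N(cs_maps["orientation"][th][i]),
                              shape)
        obar += normalize_N(acc)
    return ibar, cbar, obar


@dataclass
class ConspicuityStack:
    """All center-surround maps of one image, reusable across scale subsets.

    Building the pyramids and the 42 feature maps dominates the cost of the
    model; callers that scan several subset starts ``s`` should build the
    stack once and call :meth:`conspicuity_maps` / :meth:`saliency` per s.
    """

    cs_maps: dict
    image_shape: tuple[int, int]
    _cache: dict = field(default_factory=dict, repr=False)

    @classmethod
    def from_image(cls, image: np.ndarray) -> "ConspicuityStack":
        pyr = build_pyramids(image)
        return cls(cs_maps=center_surround_maps(pyr),
                   image_shape=pyr.image_shape)

    def conspicuity_maps(self, s: int) -> tuple[np.ndarray, np.ndarray,
                                                np.ndarray]:
        if s not in self._cache:
            self._cache[s] = conspicuity(self.cs_maps, s)
        return self._cache[s]

    def feature_images(self, s: int) -> np.ndarray:
        """Per-pixel (Ibar, Cbar, Obar) feature planes at image resolution,
        each min-max normalized; shape (h, w, 3)."""
        planes = [
            minmax_normalize(_resize_to(m, self.image_shape))[0]
            for m in self.conspicuity_maps(s)
        ]
        return np.stack(planes, axis=-1)

    def saliency(self, s: int, w_k: float | None = None,
                 image_id: str = "") -> SaliencyMap:
        ibar, cbar, obar = self.conspicuity_maps(s)
        combined = (normalize_N(ibar) + normalize_N(cbar)
                    + normalize_N(obar)) / 3.0
        grid = _resize_to(combined, self.image_shape)
        grid, degenerate = minmax_normalize(np.clip(grid, 0, None))
        smap = SaliencyMap(grid=grid, image_id=image_id, source="model_S",
                           normalization="minmax01", degenerate=degenerate)
        if w_k:
            from agesal.age_adapted_model import apply_center_bias
            smap = apply_center_bias(smap, w_k)
            smap.source = "model_S"
        return smap


def saliency_S(image: np.ndarray, s: int = 1, w_k: float | None = None,
               image_id: str = "") -> SaliencyMap:
    """Bottom-up saliency map "S" with scale subset start ``s``.

    S = mean of the re-normalized intensity, color and orientation
    conspicuity maps, upsampled to image resolution and min-max normalized.
    If ``w_k`` is given the map is modulated by the age-adapted center
    weighting.
    """
    return ConspicuityStack.from_image(image).saliency(
        s, w_k=w_k, image_id=image_id)
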