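"""Fixation tables, fixation maps and Gaussian-smoothed human saliency maps.

Coordinate convention used throughout the package: 0-based, ``x`` is the
column, ``y`` the row, origin at the top-left, with half-open pixel bounds
``[0, width) x [0, height)``.  A fixation at fractional coordinates is
assigned to the pixel obtained by rounding each axis half-away-from-zero.

The *human fixation map* of a group on one image is the binary raster that
marks every pixel fixated by at least one observer of the group (duplicates
collapse).  The *human saliency map* is that raster convolved with an
isotropic Gaussian and min-max normalized to [0, 1]; it is the empirical
attention density against which models are scored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

logger = logging.getLogger(__name__)

#: default smoothing bandwidth, in pixels, for a 1024-px-wide display
#: (roughly one degree of visual angle at a 60 cm viewing distance);
#: scaled proportionally for other image widths.
DEFAULT_SIGMA_AT_1024 = 25.0

REQUIRED_COLUMNS = ("observer", "group", "image", "x", "y")


class SchemaError(ValueError):
    """A fixation file is missing required columns."""


class ValidationError(ValueError):
    """Record contents violate the table's invariants."""


class EmptySelectionError(LookupError):
    """A (group, image) selection matched no fixation records."""


def default_sigma(width: int) -> float:
    """Smoothing sigma scaled to the image width."""
    return DEFAULT_SIGMA_AT_1024 * width / 1024.0


@dataclass(frozen=True)
class FixationRecord:
    """One fixation landing of one observer on one image."""

    observer_id: str
    group: str
    image_id: str
    x: float
    y: float
    duration_ms: float | None = None
    index: int | None = None


@dataclass
class FixationTable:
    """Validated fixation records plus per-image raster dimensions."""

    records: list[FixationRecord] = field(default_factory=list)
    image_dims: dict[str, tuple[int, int]] = field(default_factory=dict)

    def select(self, group: str | None = None,
               image_id: str | None = None) -> list[FixationRecord]:
        out = self.records
        if group is not None:
            out = [r for r in out if r.group == group]
        if image_id is not None:
            out = [r for r in out if r.image_id == image_id]
        return out

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.group, None)
        return list(seen)

    @property
    def image_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.image_id, None)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "observer": r.observer_id,
                    "group": r.group,
                    "image": r.image_id,
                    "x": r.x,
                    "y": r.y,
                    "duration_ms": r.duration_ms,
                    "index": r.index,
                }
                for r in self.records
            ]
        )


@dataclass
class FixationMap:
    """Binary raster of pooled fixation pixels for one (group, image)."""

    grid: np.ndarray
    image_id: str
    group: str

    @property
    def n_fixated_pixels(self) -> int:
        return int(self.grid.sum())


@dataclass
class SaliencyMap:
    """Non-negative 2-D raster with provenance and normalization state.

    ``source`` is one of ``human``, ``model_S``, ``model_SIC``, ``model_P``,
    ``center_map``; ``normalization`` is ``raw`` or ``minmax01``.
    ``degenerate`` flags a constant map (no usable ranking).
    """

    grid: np.ndarray
    image_id: str = ""
    source: str = "human"
    normalization: str = "raw"
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise ValueError("saliency grid must be 2-D")
        if np.any(self.grid < 0):
            raise ValueError("saliency values must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape  # type: ignore[return-value]


def minmax_normalize(grid: np.ndarray) -> tuple[np.ndarray, bool]:
    """Scale to [0, 1]; returns (scaled, degenerate) where a constant input
    maps to all-zeros with the degenerate flag set."""
    grid = np.asarray(grid, dtype=float)
    lo, hi = float(grid.min()), float(grid.max())
    if hi - lo <= 0:
        return np.zeros_like(grid), True
    return (grid - lo) / (hi - lo), False


def _round_half_away(v: np.ndarray) -> np.ndarray:
    # np.round is banker's rounding; fixation coords are non-negative so
    # floor(v + 0.5) implements round-half-away-from-zero.
    return np.floor(np.asarray(v, dtype=float) + 0.5).astype(int)


def load_fixation_table(
    path: str | Path,
    dims: Mapping[str, tuple[int, int]] | str | Path,
    known_groups: Sequence[str] | None = None,
) -> FixationTable:
    """Read a delimited fixation file and validate it against image dims.

    Parameters
    ----------
    path
        CSV/TSV with header ``observer,group,image,x,y[,duration_ms,index]``.
    dims
        Either a mapping ``image_id -> (width, height)`` or the path of a
        sidecar CSV with columns ``image,width,height``.
    known_groups
        If given, any record whose group label is not in this list raises
        :class:`ValidationError`.

    Rows whose coordinates fall outside ``[0,w) x [0,h)`` are dropped; the
    dropped count is logged as a warning.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing}; "
            f"found {list(df.columns)}"
        )

    if not isinstance(dims, Mapping):
        ddf = pd.read_csv(dims)
        need = {"image", "width", "height"}
        if not need.issubset(ddf.columns):
            raise SchemaError(f"dims sidecar must have columns {sorted(need)}")
        dims = {
            str(r.image): (int(r.width), int(r.height))
            for r in ddf.itertuples()
        }

    unknown_images = sorted(set(df["image"].astype(str)) - set(dims))
    if unknown_images:
        raise ValidationError(
            f"no dims registered for image(s): {unknown_images}"
        )
    if known_groups is not None:
        bad = sorted(set(df["group"].astype(str)) - set(known_groups))
        if bad:
            raise ValidationError(f"unknown group label(s): {bad}")

    durations = (df["duration_ms"] if "duration_ms" in df.columns
                 else pd.Series([None] * len(df)))
    orders = (df["index"] if "index" in df.columns
              else pd.Series([None] * len(df)))
    records: list[FixationRecord] = []
    dropped = 0
    for obs, grp, image_id, x, y, dur, idx in zip(
            df["observer"].astype(str), df["group"].astype(str),
            df["image"].astype(str), df["x"].astype(float),
            df["y"].astype(float), durations, orders):
        w, h = dims[image_id]
        if not (0 <= x < w and 0 <= y < h):
            dropped += 1
            continue
        records.append(
            FixationRecord(
                observer_id=obs,
                group=grp,
                image_id=image_id,
                x=x,
                y=y,
                duration_ms=None if dur is None or pd.isna(dur) else float(dur),
                index=None if idx is None or pd.isna(idx) else int(idx),
            )
        )
    if dropped:
        logger.warning("dropped %d out-of-bounds fixation rows from %s",
                       dropped, path)
    table = FixationTable(records=records, image_dims=dict(dims))
    table.n_dropped = dropped  # type: ignore[attr-defined]
    return table


def save_fixation_table(table: FixationTable, path: str | Path,
                        dims_path: str | Path | None = None) -> None:
    """Write the table (and optionally its dims sidecar) as CSV."""
    path = Path(path)
    table.to_frame().to_csv(path, index=False)
    if dims_path is not None:
        pd.DataFrame(
            [
                {"image": k, "width": w, "height": h}
                for k, (w, h) in table.image_dims.items()
            ]
        ).to_csv(dims_path, index=False)


def build_fixation_map(table: FixationTable, group: str,
                       image_id: str) -> FixationMap:
    """Binary raster of the pooled fixation pixels of ``group`` on one image.

    Each record sets ``grid[round(y), round(x)] = 1``; fixations landing on
    the same pixel collapse to a single 1.
    """
    if image_id not in table.image_dims:
        raise ValidationError(f"no dims registered for image {image_id!r}")
    recs = table.select(group=group, image_id=image_id)
    if not recs:
        raise EmptySelectionError(
            f"no fixations for group={group!r} image={image_id!r}"
        )
    w, h = table.image_dims[image_id]
    grid = np.zeros((h, w), dtype=np.uint8)
    cols = np.clip(_round_half_away([r.x for r in recs]), 0, w - 1)
    rows = np.clip(_round_half_away([r.y for r in recs]), 0, h - 1)
    grid[rows, cols] = 1
    return FixationMap(grid=grid, image_id=image_id, group=group)


def build_human_saliency_map(fmap: FixationMap,
                             sigma: float | None = None) -> SaliencyMap:
    """Gaussian-smooth a binary fixation map into an attention density.

    The binary raster is convolved with an isotropic Gaussian (zero-padded
    boundary, so fixations within ~4 sigma of the border lose some mass)
    and then min-max normalized to [0, 1].  ``sigma`` defaults to
    ``25 * width / 1024`` pixels.
    """
    if sigma is None:
        sigma = default_sigma(fmap.grid.shape[1])
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    blurred = ndimage.gaussian_filter(
        fmap.grid.astype(float), sigma=sigma, mode="constant", cval=0.0,
        truncate=4.0,
    )
    grid, degenerate = minmax_normalize(blurred)
    return SaliencyMap(
        grid=grid, image_id=fmap.image_id, source="human",
        normalization="minmax01", degenerate=degenerate,
    )


def gaussian_blur_raw(grid: np.ndarray, sigma: float) -> np.ndarray:
    """Zero-padded Gaussian blur without normalization (mass-conserving for
    interior content)."""
    return ndimage.gaussian_filter(np.asarray(grid, dtype=float),
                                   sigma=sigma, mode="constant", cval=0.0,
                                   truncate=4.0)


def write_saliency_png(smap: SaliencyMap, path: str | Path) -> None:
    """8-bit grayscale PNG for visualization (lossy quantization)."""
    grid, _ = minmax_normalize(smap.grid)
    iio.imwrite(Path(path), (grid * 255).round().astype(np.uint8))


def write_saliency_pfm(smap: SaliencyMap, path: str | Path) -> None:
    """Lossless float32 portable-float-map for exact round-trips."""
    iio.imwrite(Path(path), smap.grid.astype(np.float32))


def read_saliency_pfm(path: str | Path, image_id: str = "",
                      source: str = "human") -> SaliencyMap:
    grid = np.asarray(iio.imread(Path(path)), dtype=float)
    return SaliencyMap(grid=grid, image_id=image_id, source=source)
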