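"""Canopy openness from upward-facing hemispherical photographs.

Blue-channel extraction, Otsu thresholding restricted to the fisheye circle,
a 7 zenith-ring x 8 azimuth-segment gap-fraction grid over 0-70 degrees, and
a solid-angle-weighted openness estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np
from skimage.filters import threshold_otsu

log = logging.getLogger(__name__)

N_RINGS = 7
N_SEGMENTS = 8
MAX_ZENITH_DEG = 70.0
#: zenith angle (deg) at the rim of a 180-degree fisheye circle
RIM_ZENITH_DEG = 90.0


class CanopyError(ValueError):
    pass


@dataclass(frozen=True)
class FisheyeImage:
    """Pixel grid plus fisheye-circle geometry.

    ``data`` is (H, W) grayscale/binary or (H, W, 3) RGB. The default
    projection is equidistant: zenith angle proportional to radial pixel
    distance, reaching ``RIM_ZENITH_DEG`` at ``circle_radius_px``.
    """

    data: np.ndarray
    circle_center: Optional[tuple[float, float]] = None  # (row, col)
    circle_radius_px: Optional[float] = None

    def __post_init__(self):
        arr = np.asarray(self.data)
        object.__setattr__(self, "data", arr)
        h, w = arr.shape[:2]
        if self.circle_center is None:
            object.__setattr__(self, "circle_center", ((h - 1) / 2.0, (w - 1) / 2.0))
        if self.circle_radius_px is None:
            object.__setattr__(self, "circle_radius_px", min(h, w) / 2.0)
        if self.circle_radius_px <= 0:
            raise CanopyError("circle radius must be positive")

    @property
    def is_rgb(self) -> bool:
        return self.data.ndim == 3

    def polar(self) -> tuple[np.ndarray, np.ndarray]:
        """(zenith deg, azimuth deg in [0, 360)) for every pixel."""
        h, w = self.data.shape[:2]
        rows, cols = np.mgrid[0:h, 0:w]
        dy = rows - self.circle_center[0]
        dx = cols - self.circle_center[1]
        r = np.hypot(dy, dx)
        zenith = RIM_ZENITH_DEG * r / self.circle_radius_px
        azimuth = np.degrees(np.arctan2(dx, -dy)) % 360.0
        return zenith, azimuth


@dataclass(frozen=True)
class GapFractionGrid:
    """7 x 8 (zenith ring x azimuth segment) gap fractions over 0-70 degrees."""

    gap_fraction: np.ndarray  # NaN marks empty cells
    ring_bounds_deg: np.ndarray  # length 8 edges
    segment_bounds_deg: np.ndarray  # length 9 edges

    def ring_means(self) -> np.ndarray:
        """Azimuth-averaged gap fraction per ring (NaN if a ring is empty)."""
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.gap_fraction, axis=1)


def load_image(path: str | Path, **geometry) -> FisheyeImage:
    from PIL import Image

    arr = np.asarray(Image.open(path))
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return FisheyeImage(arr, **geometry)


def extract_blue(img: FisheyeImage) -> FisheyeImage:
    """Blue channel of an RGB fisheye image; grayscale passes through."""
    if not img.is_rgb:
        log.warning("extract_blue called on a grayscale image; passing through")
        return img
    return replace(img, data=img.data[:, :, 2])


def binarize_otsu(img: FisheyeImage) -> tuple[FisheyeImage, float]:
    """Otsu threshold over inside-circle pixels; > threshold classifies sky (1)."""
    if img.is_rgb:
        raise CanopyError("binarize_otsu expects a single-channel image")
    zenith, _ = img.polar()
    inside = zenith <= RIM_ZENITH_DEG
    px = img.data[inside]
    if px.max() == px.min():
        raise CanopyError("degenerate histogram: constant image inside the circle")
    thr = threshold_otsu(px)
    return replace(img, data=(img.data > thr).astype(np.uint8)), float(thr)


def gap_fraction_grid(binary: FisheyeImage) -> GapFractionGrid:
    """Sky-pixel fraction per (zenith ring, azimuth segment) cell."""
    if binary.is_rgb:
        raise CanopyError("gap_fraction_grid expects a binary image")
    r70 = binary.circle_radius_px * MAX_ZENITH_DEG / RIM_ZENITH_DEG
    if r70 < N_RINGS:
        raise CanopyError(
            f"circle radius maps 0-70 degrees to {r70:.1f} px; need >= {N_RINGS}"
        )
    zenith, azimuth = binary.polar()
    ring_edges = np.linspace(0.0, MAX_ZENITH_DEG, N_RINGS + 1)
    seg_edges = np.linspace(0.0, 360.0, N_SEGMENTS + 1)
    gf = np.full((N_RINGS, N_SEGMENTS), np.nan)
    inside = zenith <= MAX_ZENITH_DEG
    ring_idx = np.minimum((zenith / (MAX_ZENITH_DEG / N_RINGS)).astype(int), N_RINGS - 1)
    seg_idx = np.minimum((azimuth / (360.0 / N_SEGMENTS)).astype(int), N_SEGMENTS - 1)
    sky = binary.data > 0
    for i in range(N_RINGS):
        for j in range(N_SEGMENTS):
            cell = inside & (ring_idx == i) & (seg_idx == j)
            n = int(cell.sum())
            if n:
                gf[i, j] = sky[cell].sum() / n
    return GapFractionGrid(gf, ring_edges, seg_edges)


def canopy_openness(grid: GapFractionGrid, weighting: str = "solid-angle") -> float:
    """Openness (%) aggregating ring gap fractions over the 0-70 degree cap.

    ``solid-angle`` weights ring r by (cos th_lo - cos th_hi) / (1 - cos 70deg),
    i.e. its share of the analyzed sky cap; ``uniform`` averages rings equally.
    """
    ring_gf = grid.ring_means()
    if np.any(np.isnan(ring_gf)):
        missing = list(np.where(np.isnan(ring_gf))[0])
        raise CanopyError(f"cannot estimate openness: empty ring(s) {missing}")
    edges = np.radians(grid.ring_bounds_deg)
    if weighting == "solid-angle":
        w = (np.cos(edges[:-1]) - np.cos(edges[1:])) / (1.0 - np.cos(edges[-1]))
    elif weighting == "uniform":
        w = np.full(N_RINGS, 1.0 / N_RINGS)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return float(100.0 * np.sum(w * ring_gf))


def analyze_image(img: FisheyeImage, weighting: str = "solid-angle") -> dict:
    """Full per-image pipeline: blue channel -> Otsu -> grid -> openness."""
    gray = extract_blue(img) if img.is_rgb else img
    binary, thr = binarize_otsu(gray)
    grid = gap_fraction_grid(binary)
    return {
        "openness_pct": canopy_openness(grid, weighting=weighting),
        "threshold": thr,
        "grid": grid,
    }
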