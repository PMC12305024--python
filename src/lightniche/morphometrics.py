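"""Flight-related wing morphometrics from dorsal silhouettes.

Area, aspect ratio (moment-equivalent-ellipse axes by default) and wing
loading. Segmentation is Otsu threshold + hole filling + largest component,
assuming a single light wing on a dark background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops


class MorphometricsError(ValueError):
    pass


@dataclass(frozen=True)
class WingMetrics:
    area_mm2: float
    aspect_ratio: float
    wing_loading_g_per_mm2: float | None = None


def segment_wing(img: np.ndarray) -> np.ndarray:
    """Binary wing mask: Otsu threshold, fill holes, keep largest component."""
    arr = np.asarray(img, dtype=float)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    if arr.max() == arr.min():
        raise MorphometricsError("constant image: nothing to segment")
    mask = arr > threshold_otsu(arr)
    if not mask.any():
        raise MorphometricsError("no foreground component found")
    mask = ndimage.binary_fill_holes(mask)
    labels = label(mask)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    return labels == sizes.argmax()


def wing_area(mask: np.ndarray, scale_mm_per_px: float) -> float:
    """Pixel count times the squared scale, in mm^2."""
    if scale_mm_per_px <= 0:
        raise MorphometricsError("scale must be positive")
    n = int(np.count_nonzero(mask))
    if n == 0:
        raise MorphometricsError("empty mask")
    return n * scale_mm_per_px**2


def wing_aspect_ratio(mask: np.ndarray, method: str = "moments") -> float:
    """Major/minor axis ratio of the mask, >= 1.

    ``moments`` (default) uses the second-central-moment equivalent ellipse,
    which is rotation invariant; ``bbox`` uses the axis-aligned bounding box.
    """
    mask = np.asarray(mask, dtype=bool)
    if np.count_nonzero(mask) < 3:
        raise MorphometricsError("degenerate mask: fewer than 3 pixels")
    if method == "bbox":
        rows = np.any(mask, axis=1)
        cols = np.any(mask, axis=0)
        h = int(np.ptp(rows.nonzero()[0])) + 1
        w = int(np.ptp(cols.nonzero()[0])) + 1
        lo, hi = sorted((h, w))
        if lo == 0:
            raise MorphometricsError("degenerate mask: collinear pixels")
        return hi / lo
    if method != "moments":
        raise ValueError(f"unknown aspect-ratio method {method!r}")
    props = regionprops(mask.astype(np.uint8))[0]
    if props.axis_minor_length == 0:
        raise MorphometricsError("degenerate mask: collinear pixels")
    return props.axis_major_length / props.axis_minor_length


def wing_loading(mass_g: float, area_mm2: float) -> float:
    """Body mass divided by forewing area (g mm^-2)."""
    if area_mm2 <= 0:
        raise MorphometricsError("area must be positive")
    if mass_g < 0:
        raise MorphometricsError("mass must be non-negative")
    return mass_g / area_mm2


def measure_wing(
    img: np.ndarray, scale_mm_per_px: float, mass_g: float | None = None
) -> WingMetrics:
    mask = segment_wing(img)
    area = wing_area(mask, scale_mm_per_px)
    ar = wing_aspect_ratio(mask)
    loading = wing_loading(mass_g, area) if mass_g is not None else None
    return WingMetrics(area_mm2=area, aspect_ratio=ar, wing_loading_g_per_mm2=loading)
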