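"""Axis-uniformity segmentation of fibrotic lesions.

Birefringent (fibrotic) tissue shows a locally uniform optic-axis
orientation, while polarization-maintaining or depolarizing tissue shows a
random axis after anterior-segment compensation.  A circular-variance map
of the depth-averaged axis therefore separates lesion from background:

    v = 1 - | mean_kernel exp(i 2 theta) |        (doubled angles)

with v = 0 for perfectly uniform axes and v = 1 for opposing axes.
Low-variance regions (v < th1 = 0.21) larger than 100 pixels seed a region
growing step that adds neighboring pixels with v < th2 = 0.36; the result
is counted and converted to mm^2 (187.5 um^2 per pixel at the clinical
1024 x 250 grid over 8 x 6 mm).  A threshold sweep turns the binary mask
into a per-pixel likelihood L_h = 1 - th2*.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import json
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.draw import polygon2mask

from .enface import AxisMap
from .geometry import ScanGeometry

__all__ = [
    "SegmentationParams",
    "VarianceMap",
    "LesionMask",
    "LikelihoodMap",
    "circular_variance_map",
    "variance_bscan",
    "detect_seeds",
    "region_grow",
    "segment_lesions",
    "lesion_area",
    "area_statistics",
    "likelihood_map",
    "roi_polygon_to_mask",
    "load_roi_json",
    "save_roi_json",
]

#: Circular variance assigned to pixels whose axis is undefined; such
#: pixels can never be segmented.
INVALID_VARIANCE = 1.0


@dataclass(frozen=True)
class SegmentationParams:
    """Thresholds of the axis-uniformity segmentation.

    ``th1``: seed variance threshold (strict, v < th1).
    ``th2``: growth threshold (strict, v < th2).
    ``min_seed_px``: seed components must be strictly larger than this.
    ``dopu_threshold`` / ``intensity_factor``: voxel exclusion rules used
    upstream when building the axis map.
    ``connectivity``: 1 = 4-neighborhood, 2 = 8-neighborhood (default;
    avoids splitting diagonally connected lesion patches).
    """

    th1: float = 0.21
    th2: float = 0.36
    min_seed_px: int = 100
    dopu_threshold: float = 0.8
    intensity_factor: float = 2.0
    connectivity: int = 2

    def __post_init__(self) -> None:
        if not (0.0 <= self.th1 < self.th2 <= 1.0):
            raise ValueError("need 0 <= th1 < th2 <= 1")
        if self.min_seed_px < 1:
            raise ValueError("min_seed_px must be >= 1")
        if self.connectivity not in (1, 2):
            raise ValueError("connectivity must be 1 or 2")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class VarianceMap:
    """Circular variance of the axis map, in [0, 1]; invalid pixels -> 1."""

    v: np.ndarray
    valid: np.ndarray
    kernel: int = 5


@dataclass
class LesionMask:
    """Binary fibrosis segmentation with its geometry and optional ROI."""

    mask: np.ndarray
    geometry: ScanGeometry
    roi: np.ndarray | None = None  # polygon vertices (N, 2) in (x, y) pixels

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def area_mm2(self) -> float:
        return lesion_area(self.pixel_count, self.geometry)


@dataclass
class LikelihoodMap:
    """Per-pixel fibrosis likelihood from a threshold sweep.

    Values are 0 (never segmented) or 1 - th2* with th2* the smallest
    growth threshold whose run segments the pixel.
    """

    lh: np.ndarray
    th1_values: np.ndarray
    gap: float = 0.15


def _circular_variance(theta: np.ndarray, valid: np.ndarray, kernel: int) -> VarianceMap:
    if kernel % 2 == 0 or kernel < 1:
        raise ValueError("variance kernel must be odd-sized")
    phasor = np.where(valid, np.exp(2j * theta), 0.0)
    footprint = np.ones((kernel, kernel))
    n = ndimage.correlate(valid.astype(float), footprint, mode="constant", cval=0.0)
    re = ndimage.correlate(phasor.real, footprint, mode="constant", cval=0.0)
    im = ndimage.correlate(phasor.imag, footprint, mode="constant", cval=0.0)
    ok = n > 0
    resultant = np.hypot(re, im) / np.where(ok, n, 1.0)
    v = np.where(ok, 1.0 - resultant, INVALID_VARIANCE)
    return VarianceMap(np.clip(v, 0.0, 1.0), ok, kernel)


def circular_variance_map(axis_map: AxisMap, kernel: int = 5) -> VarianceMap:
    """Doubled-angle circular variance in a kernel x kernel neighborhood.

    Only valid neighbors contribute; kernels are cropped at the map border.
    Pixels whose neighborhood holds no valid axis are flagged and assigned
    v = 1 (never segmented).
    """
    return _circular_variance(axis_map.axis, axis_map.valid, kernel)


def variance_bscan(
    theta_bscan: np.ndarray, valid: np.ndarray | None = None, kernel: int = 41
) -> VarianceMap:
    """Circular variance of a compensated axis B-scan in the (x, z) plane.

    Severely fibrotic tissue produces columns of constant axis through
    depth, visible as low in-depth variance; the default 41 x 41 kernel
    matches the B-scan inspection display.
    """
    theta_bscan = np.asarray(theta_bscan)
    if valid is None:
        valid = np.ones(theta_bscan.shape, dtype=bool)
    return _circular_variance(theta_bscan, valid, kernel)


def detect_seeds(vmap: VarianceMap, params: SegmentationParams, roi: np.ndarray | None = None):
    """Low-variance seed regions: components of {v < th1} larger than min_seed_px."""
    candidate = vmap.v < params.th1
    if roi is not None:
        candidate &= roi
    labels = measure.label(candidate, connectivity=params.connectivity)
    if labels.max() == 0:
        return np.zeros_like(candidate)
    counts = np.bincount(labels.ravel())
    keep = counts > params.min_seed_px
    keep[0] = False
    return keep[labels]


def region_grow(
    vmap: VarianceMap,
    seeds: np.ndarray,
    params: SegmentationParams,
    roi: np.ndarray | None = None,
    geometry: ScanGeometry | None = None,
    roi_polygon: np.ndarray | None = None,
) -> LesionMask:
    """Grow seed regions into all connected pixels with v < th2.

    Iterating "add any neighbor below th2" to its fixpoint equals keeping
    the connected components of {v < th2} that contain a seed, which is how
    it is computed.  Growth (and seeds) are restricted to the ROI if given.
    """
    grow = vmap.v < params.th2
    if roi is not None:
        grow &= roi
        seeds = seeds & roi
    if geometry is None:
        geometry = ScanGeometry(vmap.v.shape[0], vmap.v.shape[1], 1)
    if not seeds.any():
        return LesionMask(np.zeros_like(grow), geometry, roi_polygon)
    labels = measure.label(grow, connectivity=params.connectivity)
    hit = np.unique(labels[seeds & grow])
    keep = np.zeros(labels.max() + 1, dtype=bool)
    keep[hit] = True
    keep[0] = False
    mask = keep[labels] | seeds  # seeds are below th1 < th2, union is a no-op guard
    return LesionMask(mask, geometry, roi_polygon)


def segment_lesions(
    vmap: VarianceMap,
    params: SegmentationParams = SegmentationParams(),
    roi: np.ndarray | None = None,
    geometry: ScanGeometry | None = None,
) -> LesionMask:
    """Seed detection followed by region growing (the full segmentation)."""
    seeds = detect_seeds(vmap, params, roi)
    return region_grow(vmap, seeds, params, roi, geometry)


def lesion_area(pixel_count: int | np.ndarray, geometry: ScanGeometry) -> float:
    """Convert a pixel count to mm^2 using the en-face pixel pitch."""
    return float(pixel_count) * geometry.pixel_area_mm2


def area_statistics(areas) -> dict:
    """Mean, population SD and coefficient of variation of repeated areas."""
    a = np.asarray(areas, dtype=float)
    mean = float(a.mean())
    sd = float(a.std(ddof=0))
    return {"mean_mm2": mean, "sd_mm2": sd, "cv": sd / mean if mean else np.nan}


def likelihood_map(
    vmap: VarianceMap,
    params: SegmentationParams = SegmentationParams(),
    roi: np.ndarray | None = None,
    th1_values: np.ndarray | None = None,
    gap: float = 0.15,
) -> LikelihoodMap:
    """Threshold-sweep likelihood of fibrosis per pixel.

    The segmentation is run for th1 in ``th1_values`` (default 0, 0.05,
    ..., 0.85: 18 runs) with th2 = th1 + ``gap``; a pixel's likelihood is
    1 - th2* for the smallest th2* that segments it, 0 if none does.
    Because the masks nest with increasing thresholds, running the sweep in
    decreasing order and overwriting yields exactly that value.
    """
    if th1_values is None:
        th1_values = np.arange(0.0, 0.851, 0.05)
    th1_values = np.asarray(th1_values, dtype=float)
    lh = np.zeros_like(vmap.v, dtype=float)
    for th1 in np.sort(th1_values)[::-1]:
        th1 = round(float(th1), 10)  # guard against arange float wobble
        th2 = round(min(th1 + gap, 1.0), 10)
        if th1 >= th2:
            continue
        p = SegmentationParams(
            th1=th1,
            th2=th2,
            min_seed_px=params.min_seed_px,
            dopu_threshold=params.dopu_threshold,
            intensity_factor=params.intensity_factor,
            connectivity=params.connectivity,
        )
        mask = segment_lesions(vmap, p, roi).mask
        lh[mask] = 1.0 - th2
    return LikelihoodMap(lh, th1_values, gap)


# ---- ROI polygons --------------------------------------------------------


def roi_polygon_to_mask(polygon: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize an (N, 2) polygon in (x, y) pixel coordinates to a mask."""
    polygon = np.asarray(polygon, dtype=float)
    if polygon.ndim != 2 or polygon.shape[1] != 2 or polygon.shape[0] < 3:
        raise ValueError("ROI polygon must be an (N>=3, 2) vertex array")
    return polygon2mask(shape, polygon)


def save_roi_json(polygon: np.ndarray, path: str | Path) -> None:
    Path(path).write_text(json.dumps({"polygon_xy": np.asarray(polygon).tolist()}))


def load_roi_json(path: str | Path) -> np.ndarray:
    return np.asarray(json.loads(Path(path).read_text())["polygon_xy"], dtype=float)
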