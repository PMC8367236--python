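"""Surfaces, integration boundary, and depth-averaged axis-orientation maps.

The depth-averaged axis map is the quantity the fibrosis segmentation works
on: per A-scan the compensated axis orientations between the reference
surface and a lower boundary anterior to the sclera are averaged in complex
space using doubled angles (axes are pi-periodic),

    resultant(x, y) = mean_z exp(i 2 theta(x, y, z)),  axis = arg/2,

excluding depolarizing voxels (DOPU < 0.8) and voxels whose intensity is
below twice the noise level.  Fibrotic tissue keeps a well-defined axis
through depth, so its average survives; everywhere else the axis is random
and the average direction is noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .compensation import CompensationResult
from .geometry import ScanGeometry
from .polcore import PolarizationVolume, wrap_axis

__all__ = [
    "SurfaceSet",
    "AxisMap",
    "estimate_noise_floor",
    "find_ilm",
    "find_reference_surface",
    "build_lower_boundary",
    "depth_averaged_axis",
    "load_surfaces_csv",
    "save_surfaces_csv",
]


@dataclass
class SurfaceSet:
    """Depth-index maps: ILM, reference (IS/OS or lesion top), lower boundary."""

    ilm: np.ndarray
    reference: np.ndarray
    lower: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        ok = self.valid
        if np.any(self.ilm[ok] > self.reference[ok]) or np.any(
            self.reference[ok] > self.lower[ok]
        ):
            raise ValueError("surface ordering violated: need ilm <= reference <= lower")


@dataclass
class AxisMap:
    """Depth-averaged axis-orientation en-face map.

    ``resultant`` is the complex mean of doubled-angle unit vectors per
    (x, y); ``n_valid`` counts contributing voxels.  Pixels with no valid
    voxel are flagged through ``valid``.
    """

    resultant: np.ndarray
    n_valid: np.ndarray

    @property
    def valid(self) -> np.ndarray:
        return self.n_valid > 0

    @property
    def axis(self) -> np.ndarray:
        """Average axis orientation in radians, [-pi/2, pi/2)."""
        return wrap_axis(np.angle(self.resultant) / 2.0)

    @property
    def axis_deg(self) -> np.ndarray:
        return np.degrees(self.axis)


def estimate_noise_floor(reflectivity: np.ndarray, margin_rows: int = 10) -> float:
    """Mean intensity of the signal-free top margin of each B-scan.

    The top ``margin_rows`` depth pixels are assumed to lie in the vitreous
    and contain only noise (the conventional signal-free region in retinal
    OCT).  If tissue reaches into the margin the estimate is inflated; that
    is a configuration error this function cannot detect.
    """
    if margin_rows < 1 or margin_rows > reflectivity.shape[-1]:
        raise ValueError("margin_rows outside volume depth")
    region = reflectivity[..., :margin_rows]
    if region.size == 0:
        raise ValueError("empty noise margin")
    return float(region.mean())


def _smooth_depth(reflectivity: np.ndarray, sigma: float) -> np.ndarray:
    return ndimage.gaussian_filter1d(reflectivity, sigma, axis=-1, mode="nearest")


def _postsmooth_surface(idx: np.ndarray, valid: np.ndarray, size: int) -> np.ndarray:
    """Transverse median filter of a detected surface; speckle outliers in
    single columns otherwise displace the surface by tens of pixels."""
    if size <= 1 or idx.ndim != 2:
        return idx
    smoothed = ndimage.median_filter(idx, size=size, mode="nearest")
    return np.where(valid, smoothed, idx)


def find_ilm(
    reflectivity: np.ndarray,
    *,
    noise_floor: float | None = None,
    factor: float = 4.0,
    sigma: float = 2.0,
    postsmooth: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """First depth where smoothed reflectivity rises above the noise.

    Adequate for phantom data; clinical volumes should import externally
    segmented surfaces instead.  Returns (depth indices, validity).
    """
    if noise_floor is None:
        noise_floor = estimate_noise_floor(reflectivity)
    smooth = _smooth_depth(reflectivity, sigma)
    above = smooth > factor * max(noise_floor, np.finfo(float).tiny)
    idx = np.argmax(above, axis=-1)
    valid = np.take_along_axis(above, idx[..., np.newaxis], axis=-1)[..., 0]
    return _postsmooth_surface(idx.astype(int), valid, postsmooth), valid


def find_reference_surface(
    reflectivity: np.ndarray,
    *,
    noise_floor: float | None = None,
    ilm: np.ndarray | None = None,
    margin: int = 5,
    sigma: float = 2.0,
    factor: float = 3.0,
    postsmooth: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Strongest smoothed reflectivity edge below the ILM estimate, per A-scan.

    Stands in for a full retinal layer segmentation: on phantoms the
    IS/OS-like reference (or the lesion top) is the strongest rising edge
    below the inner retina.  Columns whose peak reflectivity does not
    exceed ``factor`` times the noise floor are flagged invalid.  Returns
    (depths, validity).
    """
    if noise_floor is None:
        noise_floor = estimate_noise_floor(reflectivity)
    smooth = _smooth_depth(reflectivity, sigma)
    if ilm is None:
        ilm, _ = find_ilm(reflectivity, noise_floor=noise_floor, sigma=sigma)
    nz = reflectivity.shape[-1]
    start = np.clip(ilm + margin, 0, nz - 1)
    z = np.arange(nz)
    below = z >= start[..., np.newaxis]
    grad = np.gradient(smooth, axis=-1)
    idx = np.argmax(np.where(below, grad, -np.inf), axis=-1)
    peak = np.max(np.where(below, smooth, -np.inf), axis=-1)
    valid = peak > factor * noise_floor
    return _postsmooth_surface(idx.astype(int), valid, postsmooth), valid


def build_lower_boundary(
    reference: np.ndarray,
    nz: int,
    *,
    center_offset: int = 100,
    edge_offset: int = 50,
    sigma: float | None = None,
    center: tuple[float, float] | None = None,
) -> np.ndarray:
    """Lower integration boundary: reference + a 2D Gaussian offset bump.

    The offset is ``center_offset`` pixels at the map center, decaying to
    ``edge_offset`` pixels at the image edges (default sigma: a quarter of
    the shorter map dimension).  More depth pixels can be integrated in the
    macular area before the birefringent sclera is reached.  Clamped to the
    volume depth.
    """
    nx, ny = reference.shape
    if sigma is None:
        sigma = min(nx, ny) / 4.0
    if center is None:
        center = ((nx - 1) / 2.0, (ny - 1) / 2.0)
    x, y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    r2 = (x - center[0]) ** 2 + (y - center[1]) ** 2
    bump = edge_offset + (center_offset - edge_offset) * np.exp(-r2 / (2.0 * sigma**2))
    lower = reference + np.rint(bump).astype(int)
    return np.clip(lower, 0, nz - 1)


def depth_averaged_axis(
    comp: CompensationResult,
    surfaces: SurfaceSet,
    pol: PolarizationVolume,
    *,
    noise_floor: float,
    dopu_threshold: float = 0.8,
    intensity_factor: float = 2.0,
) -> AxisMap:
    """Masked complex average of the compensated axis along each A-scan.

    Voxels between ``surfaces.reference`` and ``surfaces.lower`` (inclusive)
    contribute unless they are depolarizing (DOPU < ``dopu_threshold``),
    dim (intensity < ``intensity_factor`` x ``noise_floor``) or flagged
    invalid.  Columns with invalid surfaces or no contributing voxel are
    flagged (n_valid = 0).
    """
    theta = comp.theta
    nz = theta.shape[-1]
    z = np.arange(nz)
    in_span = (z >= surfaces.reference[..., np.newaxis]) & (
        z <= surfaces.lower[..., np.newaxis]
    )
    mask = in_span & comp.valid & pol.valid
    mask &= pol.reflectivity >= intensity_factor * noise_floor
    if pol.dopu is not None:
        dopu_ok = pol.dopu >= dopu_threshold
        if pol.dopu_valid is not None:
            dopu_ok &= pol.dopu_valid
        mask &= dopu_ok
    mask &= surfaces.valid[..., np.newaxis]
    phasor = np.where(mask, np.exp(2j * theta), 0.0)
    n_valid = mask.sum(axis=-1)
    resultant = phasor.sum(axis=-1) / np.where(n_valid > 0, n_valid, 1)
    resultant[n_valid == 0] = 0.0
    return AxisMap(resultant, n_valid)


# ---- surface I/O ---------------------------------------------------------


def save_surfaces_csv(surfaces: SurfaceSet, path: str | Path) -> None:
    """Write surfaces as long-format CSV: x, y, z_index, label."""
    import pandas as pd

    nx, ny = surfaces.ilm.shape
    x, y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    frames = []
    for label, arr in (
        ("ilm", surfaces.ilm),
        ("reference", surfaces.reference),
        ("lower", surfaces.lower),
    ):
        frames.append(
            pd.DataFrame(
                {
                    "x": x.ravel(),
                    "y": y.ravel(),
                    "z_index": arr.ravel(),
                    "label": label,
                    "valid": surfaces.valid.ravel().astype(int),
                }
            )
        )
    pd.concat(frames).to_csv(path, index=False)


def load_surfaces_csv(path: str | Path) -> SurfaceSet:
    import pandas as pd

    df = pd.read_csv(path)
    nx = int(df["x"].max()) + 1
    ny = int(df["y"].max()) + 1
    maps = {}
    valid = np.ones((nx, ny), dtype=bool)
    for label, group in df.groupby("label"):
        arr = np.zeros((nx, ny), dtype=int)
        arr[group["x"], group["y"]] = group["z_index"]
        maps[label] = arr
        if "valid" in group:
            v = np.ones((nx, ny), dtype=bool)
            v[group["x"], group["y"]] = group["valid"].astype(bool)
            valid &= v
    return SurfaceSet(maps["ilm"], maps["reference"], maps["lower"], valid)
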