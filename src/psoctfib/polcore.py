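"""Jones algebra and extraction of polarization parameters from PS-OCT data.

The instrument model: a vertically polarized beam (0, 1)^T passes a
quarter-wave plate oriented at 45 deg, illuminates the eye with circular
polarization, traverses a stack of linear retarders in double pass, and is
detected in two orthogonal channels H and V after passing the quarter-wave
plate again.  For a sample that is (in double pass) equivalent to a linear
retarder with parameters (delta, theta), the channel amplitudes and phase
difference give back those parameters directly:

    R(z)  ~  A_H^2 + A_V^2
    delta = atan(A_V / A_H)            in [0, pi/2]
    theta = (pi - dPhi) / 2            wrapped to [-pi/2, pi/2)

with dPhi = arg(E_V) - arg(E_H).  With this channel ordering the extracted
axis equals the forward-model axis of the retarder (the opposite ordering
negates it).  Axis values are *relative*: the fiber optics of a real
instrument add an unknown constant offset, so only axis differences and
axis statistics are meaningful downstream.

All angles in this module are radians; degrees appear only in file I/O.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
from scipy import ndimage

from .geometry import ScanGeometry

__all__ = [
    "RetarderParams",
    "ComplexTomogram",
    "PolarizationVolume",
    "wrap_axis",
    "jones_linear_retarder",
    "double_pass_jones",
    "extract_state",
    "extract_polarization",
    "compute_dopu",
    "QUARTER_WAVE",
    "INPUT_STATE",
]


def wrap_axis(theta: np.ndarray | float) -> np.ndarray | float:
    """Wrap an axis orientation into [-pi/2, pi/2).  Axes are pi-periodic."""
    return (np.asarray(theta) + np.pi / 2) % np.pi - np.pi / 2


class RetarderParams(NamedTuple):
    """Linear retarder parameters: retardation and slow-axis orientation.

    ``delta`` is the measured (double-pass) retardation in radians,
    ``theta`` the axis orientation in radians.  ``(delta, theta)`` and
    ``(delta, theta + pi)`` describe the same retarder.
    """

    delta: float
    theta: float

    @classmethod
    def from_degrees(cls, delta_deg: float, theta_deg: float) -> "RetarderParams":
        return cls(np.radians(delta_deg), np.radians(theta_deg))

    @property
    def delta_deg(self) -> float:
        return float(np.degrees(self.delta))

    @property
    def theta_deg(self) -> float:
        return float(np.degrees(self.theta))


def jones_linear_retarder(delta, theta) -> np.ndarray:
    """Jones matrix of a linear retarder.

    J(delta, theta) =
        [[cos^2 t + sin^2 t e^{-i d},  cos t sin t (1 - e^{-i d})],
         [cos t sin t (1 - e^{-i d}),  cos^2 t e^{-i d} + sin^2 t]]

    Broadcasts over array-valued ``delta`` / ``theta``; returns shape
    ``broadcast(delta, theta).shape + (2, 2)``.
    """
    delta = np.asarray(delta, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if not (np.all(np.isfinite(delta)) and np.all(np.isfinite(theta))):
        raise ValueError("retarder parameters must be finite")
    c, s = np.cos(theta), np.sin(theta)
    e = np.exp(-1j * delta)
    off = c * s * (1.0 - e)
    out = np.empty(np.broadcast(delta, theta).shape + (2, 2), dtype=complex)
    out[..., 0, 0] = c * c + s * s * e
    out[..., 0, 1] = off
    out[..., 1, 0] = off
    out[..., 1, 1] = c * c * e + s * s
    return out


#: Quarter-wave plate at 45 deg: converts the (0,1)^T input to circular light.
QUARTER_WAVE = jones_linear_retarder(np.pi / 2, np.pi / 4)

#: Vertically polarized input Jones vector.
INPUT_STATE = np.array([0.0, 1.0])


def double_pass_jones(single_pass: np.ndarray, amplitude=1.0) -> np.ndarray:
    """Detected Jones vector for a round trip through a retarder stack.

    ``single_pass`` is the ordered single-pass product of the layer matrices
    (outermost layer leftmost), shape ``(..., 2, 2)``.  The return trip is
    the transposed product, so

        E = amplitude * 1/2 * J_Q @ P @ P^T @ J_Q @ (0, 1)^T .
    """
    P = np.asarray(single_pass)
    M = P @ np.swapaxes(P, -1, -2)
    E = 0.5 * (QUARTER_WAVE @ M @ QUARTER_WAVE) @ INPUT_STATE
    return np.asarray(amplitude)[..., np.newaxis] * E if np.ndim(amplitude) else amplitude * E


def extract_state(E: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Retardation and axis orientation of a detected Jones vector.

    ``E`` has shape ``(..., 2)`` with components (E_H, E_V).  Returns
    ``(delta, theta)`` in radians, ``delta`` in [0, pi/2], ``theta`` in
    [-pi/2, pi/2).
    """
    E = np.asarray(E)
    a_h = np.abs(E[..., 0])
    a_v = np.abs(E[..., 1])
    delta = np.arctan2(a_v, a_h)
    dphi = np.angle(E[..., 1]) - np.angle(E[..., 0])
    theta = wrap_axis((np.pi - dphi) / 2.0)
    return delta, theta


@dataclass
class ComplexTomogram:
    """Two-channel complex PS-OCT volume.

    ``e_h`` and ``e_v`` are complex arrays of shape ``(nx, ny, nz)`` holding
    the reconstructed tomogram of the horizontal and vertical detection
    channel.  The per-voxel measurement consumed by the pipeline is
    ``(A_H, A_V, dPhi) = (|e_h|, |e_v|, arg e_v - arg e_h)``.
    """

    e_h: np.ndarray
    e_v: np.ndarray
    geometry: ScanGeometry

    def __post_init__(self) -> None:
        self.e_h = np.asarray(self.e_h, dtype=complex)
        self.e_v = np.asarray(self.e_v, dtype=complex)
        if self.e_h.shape != self.e_v.shape:
            raise ValueError("channel shapes differ")
        if self.e_h.size == 0:
            raise ValueError("empty tomogram")
        if self.e_h.shape != self.geometry.volume_shape:
            raise ValueError(
                f"channel shape {self.e_h.shape} does not match geometry "
                f"{self.geometry.volume_shape}"
            )
        if not (np.all(np.isfinite(self.e_h)) and np.all(np.isfinite(self.e_v))):
            raise ValueError("non-finite amplitudes in tomogram")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.e_h.shape

    @property
    def intensity(self) -> np.ndarray:
        """Per-voxel intensity A_H^2 + A_V^2."""
        return np.abs(self.e_h) ** 2 + np.abs(self.e_v) ** 2

    # ---- container I/O ---------------------------------------------------

    def save_npz(self, path: str | Path) -> None:
        """Write both channels to ``path`` (NPZ) + a JSON geometry sidecar."""
        path = Path(path)
        np.savez(path, E_H=self.e_h, E_V=self.e_v)  # complex data compresses poorly
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps({"geometry": self.geometry.to_dict()}, indent=1))

    @classmethod
    def load_npz(cls, path: str | Path) -> "ComplexTomogram":
        path = Path(path)
        with np.load(path) as data:
            e_h, e_v = data["E_H"], data["E_V"]
        sidecar = path.with_suffix(path.suffix + ".json")
        meta = json.loads(sidecar.read_text())
        return cls(e_h, e_v, ScanGeometry.from_dict(meta["geometry"]))

    def save_tiff(self, stem: str | Path) -> None:
        """Write paired multi-page TIFFs (real+imag per channel) per B-scan page."""
        import tifffile

        stem = Path(stem)
        for name, chan in (("H", self.e_h), ("V", self.e_v)):
            # pages indexed by y; each page (z, x) real stacked over imag
            pages = np.stack(
                [np.moveaxis(chan.real, 1, 0), np.moveaxis(chan.imag, 1, 0)], axis=1
            )  # (ny, 2, nx, nz)
            tifffile.imwrite(f"{stem}_{name}.tiff", pages.astype(np.float32))
        sidecar = Path(f"{stem}_geometry.json")
        sidecar.write_text(json.dumps({"geometry": self.geometry.to_dict()}, indent=1))

    @classmethod
    def load_tiff(cls, stem: str | Path) -> "ComplexTomogram":
        import tifffile

        stem = Path(stem)
        chans = []
        for name in ("H", "V"):
            pages = tifffile.imread(f"{stem}_{name}.tiff")  # (ny, 2, nx, nz)
            chans.append(np.moveaxis(pages[:, 0], 0, 1) + 1j * np.moveaxis(pages[:, 1], 0, 1))
        meta = json.loads(Path(f"{stem}_geometry.json").read_text())
        return cls(chans[0], chans[1], ScanGeometry.from_dict(meta["geometry"]))


@dataclass
class PolarizationVolume:
    """Per-voxel polarization parameters extracted from a tomogram.

    ``reflectivity`` is in arbitrary units (A_H^2 + A_V^2), ``delta`` in
    radians in [0, pi/2], ``theta`` in radians in [-pi/2, pi/2), ``dopu``
    dimensionless in [0, 1] (``None`` until computed).  ``valid`` flags
    voxels whose polarization parameters are defined (nonzero signal).
    """

    reflectivity: np.ndarray
    delta: np.ndarray
    theta: np.ndarray
    valid: np.ndarray
    geometry: ScanGeometry
    dopu: np.ndarray | None = None
    dopu_valid: np.ndarray | None = None

    @property
    def delta_deg(self) -> np.ndarray:
        return np.degrees(self.delta)

    @property
    def theta_deg(self) -> np.ndarray:
        return np.degrees(self.theta)


def extract_polarization(tomo: ComplexTomogram) -> PolarizationVolume:
    """Per-voxel reflectivity, retardation and axis orientation.

    Voxels with A_H = A_V = 0 get reflectivity 0 and are flagged invalid
    (their delta/theta are meaningless and set to 0).
    """
    a_h = np.abs(tomo.e_h)
    a_v = np.abs(tomo.e_v)
    reflectivity = a_h**2 + a_v**2
    valid = reflectivity > 0
    delta, theta = extract_state(np.stack([tomo.e_h, tomo.e_v], axis=-1))
    delta = np.where(valid, delta, 0.0)
    theta = np.where(valid, theta, 0.0)
    return PolarizationVolume(reflectivity, delta, theta, valid, tomo.geometry)


def _kernel_sums(arr: np.ndarray, kernel: tuple[int, int]) -> np.ndarray:
    """Sum over a (x, z) window per voxel, cropped at volume borders."""
    kx, kz = kernel
    footprint = np.ones((kx, 1, kz) if arr.ndim == 3 else (kx, kz))
    return ndimage.correlate(arr, footprint, mode="constant", cval=0.0)


def compute_dopu(
    tomo: ComplexTomogram, kernel: tuple[int, int] = (5, 5)
) -> tuple[np.ndarray, np.ndarray]:
    """Degree of polarization uniformity per voxel.

    Per voxel the normalized Stokes elements are formed,

        I = A_H^2 + A_V^2,  Q = A_H^2 - A_V^2,
        U = 2 A_H A_V cos dPhi,  V = 2 A_H A_V sin dPhi,

    each of Q, U, V divided by I, then averaged over a window of ``kernel``
    = (transverse, axial) pixels within the B-scan plane, and

        DOPU = sqrt(mean(Q/I)^2 + mean(U/I)^2 + mean(V/I)^2).

    Uniform polarization in the window gives 1; fully scrambled
    polarization gives values near 0.  Zero-intensity voxels are excluded
    from the window averages; windows with no valid voxel are flagged
    invalid (second return value).
    """
    kx, kz = kernel
    if kx % 2 == 0 or kz % 2 == 0 or kx < 1 or kz < 1:
        raise ValueError("DOPU kernel must be odd-sized in both dimensions")
    a_h = np.abs(tomo.e_h)
    a_v = np.abs(tomo.e_v)
    i = a_h**2 + a_v**2
    dphi = np.angle(tomo.e_v) - np.angle(tomo.e_h)
    w = i > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        q = np.where(w, (a_h**2 - a_v**2) / i, 0.0)
        u = np.where(w, 2 * a_h * a_v * np.cos(dphi) / i, 0.0)
        v = np.where(w, 2 * a_h * a_v * np.sin(dphi) / i, 0.0)
    n = _kernel_sums(w.astype(float), kernel)
    valid = n > 0
    n_safe = np.where(valid, n, 1.0)
    qm = _kernel_sums(q, kernel) / n_safe
    um = _kernel_sums(u, kernel) / n_safe
    vm = _kernel_sums(v, kernel) / n_safe
    dopu = np.sqrt(qm**2 + um**2 + vm**2)
    dopu[~valid] = 0.0
    return dopu, valid
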