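"""Digital eye phantom: a layered forward model with full ground truth.

The phantom emulates the polarization-relevant anatomy seen by a PS-OCT
beam: a corneal linear retarder (global), an RNFL whose axis points away
from the optic nerve head and whose retardation grows toward it, a
doughnut-shaped Henle-fiber-layer retarder with radial axis about the
fovea, a bright reference surface (IS/OS or lesion top), birefringent
lesion patches with locally uniform axis, a depolarizing RPE band, and
weakly scattering tissue below.  Each voxel's detected Jones vector is the
cumulative double-pass product of all layers anterior to it, applied to the
circularly polarized illumination, scaled by the layer reflectivity:

    E = amp * 1/2 J_Q J_C J_RNFL J_HFL J_Fib R J_Fib J_HFL J_RNFL J_C J_Q (0,1)^T

Depolarization is modeled by inserting an independent random linear
retarder (uniform axis, uniform retardation) per voxel at and below the
RPE: light that has traversed a depolarizer carries no coherent
polarization state.  Fully developed speckle multiplies both channels by a
shared circular complex Gaussian; channel noise is additive complex
Gaussian.  All randomness is drawn from a single seeded generator, so equal
seeds give bit-identical volumes and different seeds share the same ground
truth.

Layer retardations in the spec are the measured (double-pass) values that
the extraction equations report; they are used directly as the per-pass
Jones matrix arguments (see :mod:`psoctfib.polcore`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .geometry import ScanGeometry, DESK_GEOMETRY
from .polcore import ComplexTomogram, jones_linear_retarder, double_pass_jones, wrap_axis

__all__ = [
    "CorneaSpec",
    "RnflSpec",
    "HflSpec",
    "LesionPatch",
    "RpeSpec",
    "ReflectivitySpec",
    "PhantomSpec",
    "GroundTruth",
    "generate_phantom",
]


@dataclass(frozen=True)
class CorneaSpec:
    """Global corneal retarder (measured double-pass value, degrees)."""

    delta_deg: float = 20.0
    theta_deg: float = 30.0


@dataclass(frozen=True)
class RnflSpec:
    """Nerve-fiber-layer retarder field.

    Axis is the azimuth about the ONH center; retardation decays away from
    the ONH with scale ``decay_mm`` from ``peak_delta_deg`` at the ONH.
    """

    peak_delta_deg: float = 4.0
    onh_center_mm: tuple[float, float] = (7.6, 3.0)
    decay_mm: float = 2.5
    thickness_px: int = 20


@dataclass(frozen=True)
class HflSpec:
    """Henle-fiber-layer retarder field: radial axis about the fovea,
    doughnut-shaped retardation peaking at ``ring_radius_mm``."""

    peak_delta_deg: float = 10.0
    fovea_center_mm: tuple[float, float] = (4.0, 3.0)
    ring_radius_mm: float = 0.75
    ring_sigma_mm: float = 0.4
    thickness_px: int = 15


@dataclass(frozen=True)
class LesionPatch:
    """Disk-shaped fibrotic patch with uniform axis.

    ``delta_deg`` is the cumulative (measured double-pass) retardation over
    the full patch thickness; birefringence accrues linearly with depth.
    """

    center_mm: tuple[float, float] = (4.0, 3.0)
    radius_mm: float = 1.1
    axis_deg: float = 25.0
    delta_deg: float = 30.0
    thickness_px: int = 40


@dataclass(frozen=True)
class RpeSpec:
    """Depolarizing RPE band: offset of its top below the reference surface."""

    offset_px: int = 45
    thickness_px: int = 12


@dataclass(frozen=True)
class ReflectivitySpec:
    """Backscattered amplitude per tissue class (arbitrary units)."""

    retina: float = 0.18
    surface: float = 1.0
    lesion: float = 0.55
    rpe: float = 0.45
    deep: float = 0.12
    surface_thickness_px: int = 3


@dataclass(frozen=True)
class PhantomSpec:
    """Complete phantom description; angles in degrees at this level."""

    geometry: ScanGeometry = DESK_GEOMETRY
    z_ilm_px: int = 60
    z_reference_px: int = 220
    tilt_px: float = 8.0
    cornea: CorneaSpec = CorneaSpec()
    rnfl: RnflSpec | None = RnflSpec()
    hfl: HflSpec | None = HflSpec()
    lesions: tuple[LesionPatch, ...] = (LesionPatch(),)
    rpe: RpeSpec | None = RpeSpec()
    reflectivity: ReflectivitySpec = ReflectivitySpec()
    speckle: bool = True
    #: additive channel noise; keeps normal retina clearly polarization
    #: preserving (DOPU >= 0.95 under the default reflectivities) while the
    #: vitreous margin stays noise-dominated, as in clinical data
    noise_std: float = 0.005

    def __post_init__(self) -> None:
        g = self.geometry
        if not (0 <= self.z_ilm_px < self.z_reference_px < g.nz):
            raise ValueError("z_ilm_px/z_reference_px: need 0 <= ilm < reference < nz")
        if self.cornea.delta_deg < 0:
            raise ValueError("cornea.delta_deg: retardation must be >= 0")
        if self.rnfl is not None and self.rnfl.peak_delta_deg < 0:
            raise ValueError("rnfl.peak_delta_deg: retardation must be >= 0")
        if self.hfl is not None and self.hfl.peak_delta_deg < 0:
            raise ValueError("hfl.peak_delta_deg: retardation must be >= 0")
        for i, les in enumerate(self.lesions):
            if les.delta_deg < 0 or les.radius_mm <= 0 or les.thickness_px < 1:
                raise ValueError(f"lesions[{i}]: invalid patch parameters")
            cx, cy = les.center_mm
            if not (0 <= cx <= g.extent_x_mm and 0 <= cy <= g.extent_y_mm):
                raise ValueError(f"lesions[{i}].center_mm: outside the map bounds")
        if self.rpe is not None:
            top = self.z_reference_px + self.rpe.offset_px
            if top + self.rpe.thickness_px > g.nz:
                raise ValueError("rpe: band extends beyond volume depth")
        if self.noise_std < 0:
            raise ValueError("noise_std: must be >= 0")

    # -- (de)serialization --------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["lesions"] = [asdict(p) for p in self.lesions]
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomSpec":
        d = yaml.safe_load(Path(path).read_text())
        d["geometry"] = ScanGeometry(**d["geometry"])
        d["cornea"] = CorneaSpec(**d["cornea"])
        for key, klass in (("rnfl", RnflSpec), ("hfl", HflSpec), ("rpe", RpeSpec)):
            if d.get(key) is not None:
                sub = dict(d[key])
                for f_ in ("onh_center_mm", "fovea_center_mm"):
                    if f_ in sub:
                        sub[f_] = tuple(sub[f_])
                d[key] = klass(**sub)
        d["reflectivity"] = ReflectivitySpec(**d["reflectivity"])
        d["lesions"] = tuple(
            LesionPatch(**{**p, "center_mm": tuple(p["center_mm"])}) for p in d["lesions"]
        )
        return cls(**d)


@dataclass
class GroundTruth:
    """Everything the pipeline is supposed to recover."""

    lesion_mask: np.ndarray  # (nx, ny) bool
    ilm: np.ndarray  # (nx, ny) int depth indices
    reference: np.ndarray
    rpe_top: np.ndarray | None
    lesion_axis: np.ndarray  # (nx, ny) radians, NaN outside lesions
    layer_fields: dict  # per-layer (delta, theta) radian fields
    spec: PhantomSpec

    def lesion_area_mm2(self) -> float:
        return float(self.lesion_mask.sum()) * self.spec.geometry.pixel_area_mm2

    def save(self, outdir: str | Path, prefix: str = "groundtruth") -> None:
        """Write the lesion mask as PNG and the surfaces as CSV."""
        import imageio.v3 as iio
        import pandas as pd

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        iio.imwrite(
            outdir / f"{prefix}_lesion_mask.png",
            (self.lesion_mask.T.astype(np.uint8) * 255),
        )
        nx, ny = self.lesion_mask.shape
        x, y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        rows = {"x": x.ravel(), "y": y.ravel(), "ilm": self.ilm.ravel(),
                "reference": self.reference.ravel()}
        if self.rpe_top is not None:
            rows["rpe_top"] = self.rpe_top.ravel()
        pd.DataFrame(rows).to_csv(outdir / f"{prefix}_surfaces.csv", index=False)


def _transverse_grids(geometry: ScanGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-center coordinates in mm, shape (nx, ny) each."""
    gx = (np.arange(geometry.nx) + 0.5) * geometry.extent_x_mm / geometry.nx
    gy = (np.arange(geometry.ny) + 0.5) * geometry.extent_y_mm / geometry.ny
    return np.meshgrid(gx, gy, indexing="ij")


def _layer_fields(spec: PhantomSpec) -> dict:
    """Per-(x, y) retardation/axis fields of RNFL, HFL and lesions (radians)."""
    x_mm, y_mm = _transverse_grids(spec.geometry)
    shape = x_mm.shape
    fields: dict[str, np.ndarray] = {}

    if spec.rnfl is not None:
        dx = x_mm - spec.rnfl.onh_center_mm[0]
        dy = y_mm - spec.rnfl.onh_center_mm[1]
        dist = np.hypot(dx, dy)
        fields["rnfl_delta"] = np.radians(spec.rnfl.peak_delta_deg) * np.exp(
            -dist / spec.rnfl.decay_mm
        )
        fields["rnfl_theta"] = wrap_axis(np.arctan2(dy, dx))
    else:
        fields["rnfl_delta"] = np.zeros(shape)
        fields["rnfl_theta"] = np.zeros(shape)

    if spec.hfl is not None:
        dx = x_mm - spec.hfl.fovea_center_mm[0]
        dy = y_mm - spec.hfl.fovea_center_mm[1]
        dist = np.hypot(dx, dy)
        fields["hfl_delta"] = np.radians(spec.hfl.peak_delta_deg) * np.exp(
            -((dist - spec.hfl.ring_radius_mm) ** 2) / (2 * spec.hfl.ring_sigma_mm**2)
        )
        fields["hfl_theta"] = wrap_axis(np.arctan2(dy, dx))
    else:
        fields["hfl_delta"] = np.zeros(shape)
        fields["hfl_theta"] = np.zeros(shape)

    lesion_mask = np.zeros(shape, dtype=bool)
    lesion_delta = np.zeros(shape)
    lesion_axis = np.full(shape, np.nan)
    lesion_thickness = np.zeros(shape, dtype=int)
    for patch in spec.lesions:
        inside = np.hypot(x_mm - patch.center_mm[0], y_mm - patch.center_mm[1]) <= patch.radius_mm
        lesion_mask |= inside
        lesion_delta[inside] = np.radians(patch.delta_deg)
        lesion_axis[inside] = np.radians(patch.axis_deg)
        lesion_thickness[inside] = patch.thickness_px
    fields["lesion_mask"] = lesion_mask
    fields["lesion_delta"] = lesion_delta
    fields["lesion_theta"] = np.where(np.isnan(lesion_axis), 0.0, lesion_axis)
    fields["lesion_axis"] = lesion_axis
    fields["lesion_thickness"] = lesion_thickness
    return fields


def _band_fraction(z: np.ndarray, top: np.ndarray, thickness) -> np.ndarray:
    """Fraction of a layer of given top/thickness traversed above depth z."""
    t = np.maximum(np.asarray(thickness, dtype=float), 1.0)
    return np.clip((z - top[..., np.newaxis]) / t[..., np.newaxis], 0.0, 1.0)


def generate_phantom(spec: PhantomSpec, seed: int) -> tuple[ComplexTomogram, GroundTruth]:
    """Forward-model a phantom volume.  Deterministic given ``seed``."""
    g = spec.geometry
    rng = np.random.default_rng(seed)
    fields = _layer_fields(spec)
    x_idx = np.arange(g.nx)

    # gently tilted surfaces (exercises the surface finder)
    tilt = np.rint(spec.tilt_px * (x_idx / max(g.nx - 1, 1) - 0.5)).astype(int)
    ilm = np.clip(spec.z_ilm_px + tilt[:, np.newaxis] + np.zeros(g.ny, dtype=int), 0, g.nz - 1)
    reference = np.clip(
        spec.z_reference_px + tilt[:, np.newaxis] + np.zeros(g.ny, dtype=int), 0, g.nz - 1
    )
    rpe_top = None
    if spec.rpe is not None:
        rpe_top = np.clip(reference + spec.rpe.offset_px, 0, g.nz - 1)

    # random draws made once, in a fixed order, for determinism
    depol_delta = rng.uniform(0.0, np.pi, size=g.volume_shape)
    depol_theta = rng.uniform(-np.pi / 2, np.pi / 2, size=g.volume_shape)
    if spec.speckle:
        speckle = (
            rng.standard_normal(g.volume_shape) + 1j * rng.standard_normal(g.volume_shape)
        ) / np.sqrt(2.0)
    noise_h = noise_v = None
    if spec.noise_std > 0:
        noise_h = spec.noise_std * (
            rng.standard_normal(g.volume_shape) + 1j * rng.standard_normal(g.volume_shape)
        )
        noise_v = spec.noise_std * (
            rng.standard_normal(g.volume_shape) + 1j * rng.standard_normal(g.volume_shape)
        )

    refl = spec.reflectivity
    z = np.arange(g.nz)
    e_h = np.zeros(g.volume_shape, dtype=complex)
    e_v = np.zeros(g.volume_shape, dtype=complex)
    j_cornea = jones_linear_retarder(
        np.radians(spec.cornea.delta_deg), np.radians(spec.cornea.theta_deg)
    )

    for j in range(g.ny):  # per B-scan to bound memory
        ilm_j = ilm[:, j]
        ref_j = reference[:, j]
        zz = np.broadcast_to(z, (g.nx, g.nz))

        # cumulative per-pass retarders above each voxel
        rnfl_t = spec.rnfl.thickness_px if spec.rnfl is not None else 1
        hfl_t = spec.hfl.thickness_px if spec.hfl is not None else 1
        frac_rnfl = _band_fraction(zz, ilm_j, rnfl_t)
        frac_hfl = _band_fraction(zz, ref_j - hfl_t, hfl_t)
        les_t = fields["lesion_thickness"][:, j]
        frac_les = _band_fraction(zz, ref_j, np.maximum(les_t, 1))
        frac_les[les_t == 0] = 0.0

        P = np.broadcast_to(j_cornea, (g.nx, g.nz, 2, 2))
        P = P @ jones_linear_retarder(
            fields["rnfl_delta"][:, j, np.newaxis] * frac_rnfl,
            fields["rnfl_theta"][:, j, np.newaxis] + np.zeros_like(frac_rnfl),
        )
        P = P @ jones_linear_retarder(
            fields["hfl_delta"][:, j, np.newaxis] * frac_hfl,
            fields["hfl_theta"][:, j, np.newaxis] + np.zeros_like(frac_hfl),
        )
        P = P @ jones_linear_retarder(
            fields["lesion_delta"][:, j, np.newaxis] * frac_les,
            fields["lesion_theta"][:, j, np.newaxis] + np.zeros_like(frac_les),
        )
        if rpe_top is not None:
            in_depol = zz >= rpe_top[:, j, np.newaxis]
            j_rnd = jones_linear_retarder(
                np.where(in_depol, depol_delta[:, j, :], 0.0),
                np.where(in_depol, depol_theta[:, j, :], 0.0),
            )
            P = P @ j_rnd

        # reflectivity amplitude per voxel
        amp = np.zeros((g.nx, g.nz))
        amp[zz >= ilm_j[:, np.newaxis]] = refl.retina
        in_surface = (zz >= ref_j[:, np.newaxis]) & (
            zz < ref_j[:, np.newaxis] + refl.surface_thickness_px
        )
        in_lesion = (
            fields["lesion_mask"][:, j, np.newaxis]
            & (zz >= ref_j[:, np.newaxis])
            & (zz < ref_j[:, np.newaxis] + les_t[:, np.newaxis])
        )
        amp[in_lesion] = refl.lesion
        amp[in_surface] = refl.surface
        if rpe_top is not None:
            in_rpe = (zz >= rpe_top[:, j, np.newaxis]) & (
                zz < rpe_top[:, j, np.newaxis] + spec.rpe.thickness_px
            )
            below = zz >= rpe_top[:, j, np.newaxis] + spec.rpe.thickness_px
            amp[in_rpe] = refl.rpe
            amp[below] = refl.deep

        E = double_pass_jones(P, amplitude=amp)
        e_h[:, j, :] = E[..., 0]
        e_v[:, j, :] = E[..., 1]

    if spec.speckle:
        e_h *= speckle
        e_v *= speckle
    if noise_h is not None:
        e_h += noise_h
        e_v += noise_v

    tomo = ComplexTomogram(e_h, e_v, g)
    truth = GroundTruth(
        lesion_mask=fields["lesion_mask"],
        ilm=ilm,
        reference=reference,
        rpe_top=rpe_top,
        lesion_axis=fields["lesion_axis"],
        layer_fields={
            k: fields[k] for k in ("rnfl_delta", "rnfl_theta", "hfl_delta", "hfl_theta")
        },
        spec=spec,
    )
    return tomo, truth
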