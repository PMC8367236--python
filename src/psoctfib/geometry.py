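"""Scan geometry: grid sizes and physical pixel pitches.

The en-face grid covers a fixed retinal field (default 8 x 6 mm for a
standard-length eye), so transverse pixel pitch follows from the number of
A-scans and B-scans.  Depth is sampled at a fixed axial pitch in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict


@dataclass(frozen=True)
class ScanGeometry:
    """Volume grid and physical extents.

    Axes follow (x, y, z): ``x`` indexes A-scans within a B-scan, ``y``
    indexes B-scans, ``z`` is depth (0 = anterior-most pixel).
    """

    nx: int
    ny: int
    nz: int
    extent_x_mm: float = 8.0
    extent_y_mm: float = 6.0
    dz_um: float = 1.39

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.nz) <= 0:
            raise ValueError("grid sizes must be positive")
        if self.extent_x_mm <= 0 or self.extent_y_mm <= 0 or self.dz_um <= 0:
            raise ValueError("physical extents must be positive")

    @property
    def pitch_x_um(self) -> float:
        return self.extent_x_mm * 1000.0 / self.nx

    @property
    def pitch_y_um(self) -> float:
        return self.extent_y_mm * 1000.0 / self.ny

    @property
    def pixel_area_um2(self) -> float:
        """En-face area of one map pixel in square micrometres."""
        return self.pitch_x_um * self.pitch_y_um

    @property
    def pixel_area_mm2(self) -> float:
        return self.pixel_area_um2 * 1e-6

    @property
    def enface_shape(self) -> tuple[int, int]:
        return (self.nx, self.ny)

    @property
    def volume_shape(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.nz)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScanGeometry":
        return cls(**d)


#: Acquisition grid of the clinical instrument: 250 B-scans of 1024 A-scans
#: over 8 x 6 mm (one pixel = 187.5 um^2), 1024 depth pixels.
CLINICAL_GEOMETRY = ScanGeometry(nx=1024, ny=250, nz=1024)

#: Desk-scale default used by the phantom: same retinal field, coarser
#: transverse sampling, 512 depth pixels at the same axial pitch.
DESK_GEOMETRY = ScanGeometry(nx=256, ny=64, nz=512)
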