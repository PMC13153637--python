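"""Imaging geometry of the orthogonal-kV system.

The treatment machine images the patient with two x-ray projections whose
axes lie at +-45 degrees from vertical in the axial plane; the vertical
axis of each 2D image runs along the patient superior-inferior direction.
A 3D target displacement (x, y, z) in the patient frame therefore appears
as a left-right shift ``I_A`` in view A, an independent left-right shift
``I_B`` in view B, and a *common* superior-inferior shift ``J_AB`` in both
views:

    x = R (I_A + I_B)
    y = R (I_B - I_A)
    z = -J_AB

with R = sqrt(2)/2.  Patient axes: x positive toward patient left,
y positive anterior, z positive superior.  Image axes: I positive toward
increasing column index, J positive toward increasing row index (the
display shows inferior downwards, which makes z = -J_AB literal).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Back-projection constant relating oblique-view image shifts to
#: patient-frame displacements: R = sqrt(2)/2.
R_OBLIQUE: float = math.sqrt(2.0) / 2.0


@dataclass(frozen=True)
class ImagingGeometry:
    """Square-detector parallel-ray geometry of the two oblique views.

    Parameters
    ----------
    image_size:
        Pixels per side of the (square) projection images.
    pixel_spacing:
        mm per pixel at the target plane.
    """

    image_size: int = 320
    pixel_spacing: float = 1.0

    def __post_init__(self) -> None:
        if self.image_size < 64:
            raise ValueError(f"image_size must be >= 64, got {self.image_size}")
        if not (self.pixel_spacing > 0):
            raise ValueError(f"pixel_spacing must be > 0, got {self.pixel_spacing}")

    @property
    def fov_mm(self) -> float:
        """Side length of the imaged field of view in mm."""
        return self.image_size * self.pixel_spacing


@dataclass(frozen=True)
class TargetPosition:
    """Target-volume position (mm, patient frame) at one image instance."""

    x: float
    y: float
    z: float
    fraction_index: int = 0
    image_index: int = 0

    def __post_init__(self) -> None:
        if not all(map(math.isfinite, (self.x, self.y, self.z))):
            raise ValueError("TargetPosition components must be finite")
        if self.fraction_index < 0 or self.image_index < 0:
            raise ValueError("indices must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass(frozen=True)
class CoupledShift:
    """Image-plane shifts linking the two oblique views.

    ``I_A`` and ``I_B`` are the left-right (column) shifts of views A and
    B; ``J_AB`` is the superior-inferior (row) shift shared by both views.
    ``unit`` flags whether the values are in pixels or mm.
    """

    I_A: float
    I_B: float
    J_AB: float
    unit: str = "mm"

    def __post_init__(self) -> None:
        if self.unit not in ("mm", "pixels"):
            raise ValueError(f"unit must be 'mm' or 'pixels', got {self.unit!r}")
        if not all(map(math.isfinite, (self.I_A, self.I_B, self.J_AB))):
            raise ValueError("CoupledShift components must be finite")

    def to_mm(self, geometry: ImagingGeometry) -> "CoupledShift":
        if self.unit == "mm":
            return self
        s = geometry.pixel_spacing
        return CoupledShift(self.I_A * s, self.I_B * s, self.J_AB * s, unit="mm")

    def to_pixels(self, geometry: ImagingGeometry) -> "CoupledShift":
        if self.unit == "pixels":
            return self
        s = geometry.pixel_spacing
        return CoupledShift(self.I_A / s, self.I_B / s, self.J_AB / s, unit="pixels")

    def as_array(self) -> np.ndarray:
        return np.array([self.I_A, self.I_B, self.J_AB], dtype=float)


def backproject(shift: CoupledShift) -> np.ndarray:
    """Map a coupled image-plane shift (mm) to a 3D target offset (mm).

    Returns ``(x, y, z) = (R (I_A + I_B), R (I_B - I_A), -J_AB)``.
    """
    if shift.unit != "mm":
        raise ValueError("backproject expects a CoupledShift in mm; convert first")
    a, b, j = shift.I_A, shift.I_B, shift.J_AB
    return np.array(
        [R_OBLIQUE * (a + b), R_OBLIQUE * (b - a), -j],
        dtype=float,
    )


def project(offset) -> CoupledShift:
    """Map a 3D target offset (mm) to the coupled image-plane shift (mm).

    Algebraic inverse of :func:`backproject`:
    ``(I_A, I_B, J_AB) = (R (x - y), R (x + y), -z)``.
    """
    offset = np.asarray(offset, dtype=float)
    if offset.shape != (3,):
        raise ValueError(f"offset must be a 3-vector, got shape {offset.shape}")
    if not np.all(np.isfinite(offset)):
        raise ValueError("offset must be finite")
    x, y, z = offset
    return CoupledShift(
        I_A=R_OBLIQUE * (x - y),
        I_B=R_OBLIQUE * (x + y),
        J_AB=-z,
        unit="mm",
    )
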