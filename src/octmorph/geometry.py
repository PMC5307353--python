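"""Physically scaled measurement primitives.

OCT structure images have anisotropic pixels: the axial (depth) pitch is set
by the spectrometer and the refractive index of the imaging medium, while the
lateral pitch is set by the beam scan step, so a pixel is generally not
square. Every measurement therefore scales each pixel displacement by its own
per-axis factor before combining: distances are the Euclidean norm of the
per-axis scaled displacements, areas are the pixel-space shoelace area
multiplied by both scale factors.

Conventions
-----------
* Coordinates are continuous ``(axial, lateral)`` pixel positions, 0-based,
  with pixel ``(0, 0)`` centred on the first sample. Sub-pixel positions are
  legal everywhere — landmarks come from interpolated edge detection, not from
  a lattice.
* Polygons are vertex polygons (shoelace on the vertex coordinates), closed
  implicitly; orientation does not matter.
* Lengths are micrometres, areas square micrometres. Millimetres appear only
  at table export.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ScalingParams",
    "point_distance",
    "polyline_length",
    "polygon_area",
    "record_value",
    "remeasure",
]

Point = tuple[float, float]


@dataclass(frozen=True)
class ScalingParams:
    """Per-axis physical pixel pitch in µm/pixel.

    ``axial_scale`` applies to the first coordinate (depth), ``lateral_scale``
    to the second. The two are independent and usually different.
    """

    axial_scale: float
    lateral_scale: float

    def __post_init__(self) -> None:
        if not (self.axial_scale > 0 and self.lateral_scale > 0):
            raise ValueError(
                f"scales must be positive, got axial={self.axial_scale}, "
                f"lateral={self.lateral_scale}"
            )

    @classmethod
    def from_meta(cls, meta) -> "ScalingParams":
        """Build from :class:`~octmorph.container_io.AcquisitionMeta`.

        The axial pitch in the medium is the in-air pitch divided by the
        refractive index; it is derived here, never stored.
        """
        return cls(
            axial_scale=meta.axial_pixel_pitch_air / meta.refractive_index,
            lateral_scale=meta.lateral_pixel_pitch,
        )


def _check_finite(points: Sequence[Point]) -> None:
    arr = np.asarray(points, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("coordinates must be finite")


def point_distance(p1: Point, p2: Point, s: ScalingParams) -> float:
    """Physical distance in µm between two (axial, lateral) pixel positions.

    Each axis displacement is scaled by its own pitch before the Euclidean
    combination: ``sqrt((Δz·axial_scale)² + (Δx·lateral_scale)²)``.
    """
    _check_finite([p1, p2])
    dz = (p2[0] - p1[0]) * s.axial_scale
    dx = (p2[1] - p1[1]) * s.lateral_scale
    return math.hypot(dz, dx)


def polyline_length(points: Sequence[Point], s: ScalingParams) -> float:
    """Total physical length in µm of an open polyline (≥ 2 points)."""
    if len(points) < 2:
        raise ValueError(f"polyline needs at least 2 points, got {len(points)}")
    _check_finite(points)
    return float(
        sum(point_distance(points[i], points[i + 1], s) for i in range(len(points) - 1))
    )


def polygon_area(points: Sequence[Point], s: ScalingParams) -> float:
    """Physical area in µm² of an implicitly closed vertex polygon.

    The shoelace sum is evaluated in pixel space and then multiplied by both
    scale factors; the result is orientation- and translation-invariant.
    """
    if len(points) < 3:
        raise ValueError(f"polygon needs at least 3 points, got {len(points)}")
    _check_finite(points)
    pts = np.asarray(points, dtype=float)
    z = pts[:, 0]
    x = pts[:, 1]
    shoelace = 0.5 * np.abs(np.dot(z, np.roll(x, -1)) - np.dot(x, np.roll(z, -1)))
    return float(shoelace * s.axial_scale * s.lateral_scale)


def record_value(kind: str, points: Sequence[Point], s: ScalingParams) -> float:
    """Value of a measurement of the given kind: µm for lengths, µm² for areas."""
    if kind == "distance":
        if len(points) != 2:
            raise ValueError(f"distance needs exactly 2 points, got {len(points)}")
        return point_distance(points[0], points[1], s)
    if kind == "polyline":
        return polyline_length(points, s)
    if kind == "polygon":
        return polygon_area(points, s)
    raise ValueError(f"unknown measurement kind {kind!r}")


def remeasure(record, s: ScalingParams, verify: bool = False, rtol: float = 1e-9):
    """Recompute a measurement record's value from its points under scaling `s`.

    Returns a new record with the recomputed value. With ``verify=True`` the
    recomputed value is asserted to agree with the stored one to relative
    tolerance ``rtol`` (the sidecar round-trip check); a mismatch raises
    ``ValueError`` — use this to detect stale persisted values.
    """
    value = record_value(record.kind, record.points, s)
    if verify:
        stored = record.value
        scale = max(abs(stored), abs(value), 1e-300)
        if abs(stored - value) / scale > rtol:
            raise ValueError(
                f"record {record.id!r}: stored value {stored} disagrees with "
                f"recomputed {value} beyond rtol={rtol}"
            )
    return dataclasses.replace(record, value=value)
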