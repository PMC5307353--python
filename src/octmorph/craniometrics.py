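"""Craniofacial cartilage quantitation on coronal-plane images.

Three cartilage elements — one per cranial neural-crest stream — are
measured on a single coronal frame, confined to one side of the tadpole
(injecting one blastomere at the two-cell stage leaves the other side as an
internal control):

* **Meckel's cartilage** (mandibular stream): length of the polyline along
  the mid-corpus between the anterior tip and the ceratohyal articulation;
  area of a closed outline when one is supplied.
* **Ceratohyal cartilage** (hyoid stream): length of the longest axis from
  the midline to the most lateral margin; outline area when supplied.
* **Anterior gill cartilage** (branchial stream): mid-corpus polyline length
  between the middle and lateral borders.

Landmark points are inputs — annotation files or phantom ground truth; the
operator clicks them in practice, so automatic segmentation is deliberately
out of scope. Plane selection ("scroll until the largest mid-lateral portion
is visible") is modelled by :func:`select_frame`, a deterministic surrogate
that picks the frame maximizing mean ROI intensity, with a manual override.
All numbers reduce to :mod:`octmorph.geometry` primitives.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import DataError
from .geometry import ScalingParams, polygon_area, polyline_length

__all__ = [
    "CranioMetrics",
    "measure_meckel",
    "measure_ceratohyal",
    "measure_gill",
    "measure_all",
    "compare_sides",
    "select_frame",
    "load_annotations",
]


@dataclass
class CranioMetrics:
    """Cartilage measurements for one side of one tadpole (µm, µm²)."""

    side: str
    meckel_length: Optional[float] = None
    meckel_area: Optional[float] = None
    ceratohyal_length: Optional[float] = None
    ceratohyal_area: Optional[float] = None
    gill_length: Optional[float] = None

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and v < 0:
                raise ValueError(f"{f.name} must be >= 0, got {v}")


def _length_and_area(midline_points, outline, s, what: str):
    if len(midline_points) < 2:
        raise ValueError(f"{what}: need >= 2 mid-corpus points, got {len(midline_points)}")
    length = polyline_length(midline_points, s)
    area = None
    if outline is not None:
        if len(outline) < 3:
            warnings.warn(
                f"{what}: outline has {len(outline)} point(s) (< 3); area omitted",
                UserWarning,
                stacklevel=3,
            )
        else:
            area = polygon_area(outline, s)
    return length, area


def measure_meckel(frame, midcorpus_points, s: ScalingParams, outline=None):
    """(length µm, area µm² or None) of Meckel's cartilage.

    Length runs along the mid-corpus polyline; area needs a closed outline
    of ≥ 3 points (fewer triggers a notice and area is omitted).
    """
    return _length_and_area(midcorpus_points, outline, s, "meckel")


def measure_ceratohyal(frame, axis_points, s: ScalingParams, outline=None):
    """(length µm, area µm² or None) of the ceratohyal cartilage.

    The axis runs from the midline to the most lateral margin of the
    triangle.
    """
    return _length_and_area(axis_points, outline, s, "ceratohyal")


def measure_gill(frame, midline_points, s: ScalingParams) -> float:
    """Mid-corpus polyline length (µm) of the most anterior gill cartilage."""
    if len(midline_points) < 2:
        raise ValueError(f"gill: need >= 2 points, got {len(midline_points)}")
    length = polyline_length(midline_points, s)
    if length == 0:
        raise ValueError("gill: annotation points coincide (zero length)")
    return length


def measure_all(frame, annotations: dict, s: ScalingParams, side: str = "left") -> CranioMetrics:
    """Run all three measurements from one annotation dict.

    Recognised keys (each a list of (axial, lateral) pixel points):
    ``meckel_midcorpus``, ``meckel_outline``, ``ceratohyal_axis``,
    ``ceratohyal_outline``, ``gill_midline``. Missing elements are skipped.
    """
    m = CranioMetrics(side=side)
    if "meckel_midcorpus" in annotations:
        m.meckel_length, m.meckel_area = measure_meckel(
            frame, annotations["meckel_midcorpus"], s, annotations.get("meckel_outline")
        )
    if "ceratohyal_axis" in annotations:
        m.ceratohyal_length, m.ceratohyal_area = measure_ceratohyal(
            frame, annotations["ceratohyal_axis"], s, annotations.get("ceratohyal_outline")
        )
    if "gill_midline" in annotations:
        m.gill_length = measure_gill(frame, annotations["gill_midline"], s)
    return m


_METRIC_NAMES = ("meckel_length", "meckel_area", "ceratohyal_length", "ceratohyal_area", "gill_length")


def compare_sides(left: CranioMetrics, right: CranioMetrics) -> dict:
    """Right/left ratio per metric; 1.0 for identical sides.

    Metrics absent on either side are omitted from the result.
    """
    ratios = {}
    for name in _METRIC_NAMES:
        lv, rv = getattr(left, name), getattr(right, name)
        if lv is None or rv is None or lv == 0:
            continue
        ratios[name] = rv / lv
    return ratios


def select_frame(movie: Sequence, roi, override: Optional[int] = None) -> int:
    """Index of the frame maximizing mean ROI intensity (operator surrogate).

    ``override`` short-circuits to a manually chosen frame, mirroring the
    operator's prerogative to pick the plane by eye.
    """
    movie = list(movie)
    if override is not None:
        if not (0 <= override < len(movie)):
            raise ValueError(f"override frame {override} out of range 0..{len(movie) - 1}")
        return override
    (z0, z1), (x0, x1) = roi
    means = [
        float(np.asarray(getattr(fr, "values", fr))[z0:z1, x0:x1].mean()) for fr in movie
    ]
    return int(np.argmax(means))


def load_annotations(path) -> dict:
    """Load a structured-text annotation file (JSON of named point lists).

    Schema: ``{"frame_index": int, "side": "left"|"right",
    "<element>_<role>": [[axial, lateral], ...], ...}``.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"annotation file not found: {path}")
    payload = json.loads(path.read_text())
    if not isinstance(payload, dict):
        raise DataError(f"{path}: annotation file must hold a JSON object")
    out = {}
    for key, val in payload.items():
        if key in ("frame_index", "side"):
            out[key] = val
        else:
            out[key] = [tuple(map(float, p)) for p in val]
    return out
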