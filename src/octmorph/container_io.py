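"""Open raw-fringe container, measurement sidecars, and tabular export.

The instrument that motivated this package writes a proprietary raw file; the
package instead defines an open, lossless, single-file HDF5 dialect that
carries the unprocessed spectrometer fringes together with the acquisition
metadata needed to reconstruct and physically scale the images:

``/meta``
    attributes holding every :class:`AcquisitionMeta` field.
``/frames/00000, /frames/00001, ...``
    one 2-D float64 dataset per B-scan, spectral sample index k (rows) ×
    lateral A-scan index x (columns).
``/backgrounds/00000, ...``
    optional per-frame reference spectrum (vector over k).

Measurements are persisted in a plain-text JSON sidecar named
``<source>.measurements`` next to the source file, keyed by the SHA-256 of
the source so stale sidecars are detectable (a mismatch warns but still
returns the records). All persisted coordinates are 0-based pixel indices,
axial axis first.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd

from .errors import ContainerError, DataError, StaleSidecarWarning

__all__ = [
    "AcquisitionMeta",
    "SpectralFrame",
    "MeasurementRecord",
    "write_container",
    "read_container",
    "sidecar_path",
    "save_measurements",
    "load_measurements",
    "export_table",
    "export_tiff",
    "sha256_of",
]

SENSITIVITY_MODES = ("high_speed", "high_sensitivity")
MEASUREMENT_KINDS = ("distance", "polyline", "polygon")

SIDECAR_FORMAT = "octmorph-measurements"
SIDECAR_VERSION = 1


@dataclass(frozen=True)
class AcquisitionMeta:
    """Acquisition metadata for one raw-fringe stack.

    Defaults mirror a 1325 nm spectral-domain system imaging tadpoles in
    water: 91 kHz A-scan rate in high-speed (cardiac) mode, 12 µm axial pixel
    pitch in air which the refractive index of water (1.33) brings to ~9 µm
    in the medium. The in-medium axial pitch is always derived, never stored.
    """

    n_spectral_samples: int
    n_ascans_per_frame: int
    n_frames: int
    frame_rate: float
    axial_pixel_pitch_air: float = 12.0
    lateral_pixel_pitch: float = 15.0
    refractive_index: float = 1.33
    ascan_rate: float = 91000.0
    sensitivity_mode: str = "high_speed"

    def __post_init__(self) -> None:
        for name in ("n_spectral_samples", "n_ascans_per_frame", "n_frames"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 1):
                raise ValueError(f"{name} must be an integer >= 1, got {v!r}")
        for name in ("frame_rate", "axial_pixel_pitch_air", "lateral_pixel_pitch", "ascan_rate"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)!r}")
        if not self.refractive_index >= 1:
            raise ValueError(f"refractive_index must be >= 1, got {self.refractive_index!r}")
        if self.sensitivity_mode not in SENSITIVITY_MODES:
            raise ValueError(
                f"sensitivity_mode must be one of {SENSITIVITY_MODES}, "
                f"got {self.sensitivity_mode!r}"
            )

    @property
    def axial_pixel_pitch_medium(self) -> float:
        """Axial pixel pitch in the imaging medium, µm/pixel (derived)."""
        return self.axial_pixel_pitch_air / self.refractive_index


@dataclass
class SpectralFrame:
    """Raw interferometer fringes for one B-scan.

    ``fringes`` is real-valued, spectral sample k (rows) × lateral position x
    (columns), in arbitrary detector units. ``background`` is an optional
    reference spectrum subtracted before the Fourier transform.
    """

    fringes: np.ndarray
    meta: AcquisitionMeta
    background: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.fringes = np.asarray(self.fringes, dtype=float)
        if self.fringes.ndim != 2:
            raise ValueError("fringes must be a 2-D matrix (k x lateral)")
        if not np.all(np.isfinite(self.fringes)):
            raise ValueError("fringes must be finite")
        if self.fringes.shape[0] != self.meta.n_spectral_samples:
            raise ValueError(
                f"fringes have {self.fringes.shape[0]} spectral samples but "
                f"meta.n_spectral_samples={self.meta.n_spectral_samples}"
            )
        if self.background is not None:
            self.background = np.asarray(self.background, dtype=float)
            if self.background.shape != (self.meta.n_spectral_samples,):
                raise ValueError("background must be a vector over spectral samples")


@dataclass
class MeasurementRecord:
    """A named distance/polyline/polygon measurement in physical units.

    ``points`` are ordered ``(axial, lateral)`` pixel coordinates (fractional
    allowed); ``value`` is µm for distance/polyline, µm² for polygon. Each
    record carries a colour index so overlays stay identifiable.
    """

    id: str
    kind: str
    points: list
    frame_index: int
    value: float
    label: str = ""
    color_index: int = 0

    def __post_init__(self) -> None:
        if self.kind not in MEASUREMENT_KINDS:
            raise ValueError(f"kind must be one of {MEASUREMENT_KINDS}, got {self.kind!r}")
        self.points = [(float(p[0]), float(p[1])) for p in self.points]
        n = len(self.points)
        if self.kind == "distance" and n != 2:
            raise ValueError(f"distance record needs exactly 2 points, got {n}")
        if self.kind == "polyline" and n < 2:
            raise ValueError(f"polyline record needs >= 2 points, got {n}")
        if self.kind == "polygon" and n < 3:
            raise ValueError(f"polygon record needs >= 3 points, got {n}")


# ---------------------------------------------------------------------------
# container read/write
# ---------------------------------------------------------------------------

_META_FIELDS = [f.name for f in dataclasses.fields(AcquisitionMeta)]


def write_container(frames: Sequence[SpectralFrame], path) -> None:
    """Write a sequence of frames sharing one AcquisitionMeta to `path`.

    Lossless: `read_container` returns bit-identical fringes and metadata.
    Frames with inconsistent metadata are rejected with the offending field
    named.
    """
    frames = list(frames)
    if not frames:
        raise DataError("cannot write an empty container")
    meta = frames[0].meta
    for i, fr in enumerate(frames[1:], start=1):
        if fr.meta != meta:
            for name in _META_FIELDS:
                if getattr(fr.meta, name) != getattr(meta, name):
                    raise DataError(
                        f"frame {i} metadata field {name!r} "
                        f"({getattr(fr.meta, name)!r}) differs from frame 0 "
                        f"({getattr(meta, name)!r})"
                    )
    if meta.n_frames != len(frames):
        meta = dataclasses.replace(meta, n_frames=len(frames))
    with h5py.File(path, "w") as h5:
        g = h5.create_group("meta")
        for name in _META_FIELDS:
            g.attrs[name] = getattr(meta, name)
        fg = h5.create_group("frames")
        bg = h5.create_group("backgrounds")
        for i, fr in enumerate(frames):
            fg.create_dataset(f"{i:05d}", data=fr.fringes, dtype="f8")
            if fr.background is not None:
                bg.create_dataset(f"{i:05d}", data=fr.background, dtype="f8")


def read_container(path) -> list[SpectralFrame]:
    """Read frames back in acquisition order; errors name what is broken."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"container not found: {path}")
    try:
        h5 = h5py.File(path, "r")
    except OSError as exc:
        raise ContainerError(f"not a readable container: {path} ({exc})") from exc
    with h5:
        if "meta" not in h5:
            raise ContainerError("missing /meta group")
        attrs = h5["meta"].attrs
        kwargs = {}
        for name in _META_FIELDS:
            if name not in attrs:
                raise ContainerError(f"missing metadata field {name!r}")
            v = attrs[name]
            if isinstance(v, bytes):
                v = v.decode()
            if name.startswith("n_"):
                v = int(v)
            kwargs[name] = v
        try:
            meta = AcquisitionMeta(**kwargs)
        except ValueError as exc:
            raise ContainerError(f"corrupt metadata: {exc}") from exc
        frames = []
        fg = h5.get("frames")
        bgs = h5.get("backgrounds")
        for i in range(meta.n_frames):
            key = f"{i:05d}"
            if fg is None or key not in fg:
                raise ContainerError(f"frame {i} missing")
            background = None
            if bgs is not None and key in bgs:
                background = np.asarray(bgs[key])
            frames.append(
                SpectralFrame(fringes=np.asarray(fg[key]), meta=meta, background=background)
            )
    return frames


# ---------------------------------------------------------------------------
# measurement sidecar
# ---------------------------------------------------------------------------


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def sidecar_path(source_path) -> Path:
    """Deterministic sidecar location: `<source>.measurements` next to it."""
    source_path = Path(source_path)
    return source_path.with_name(source_path.name + ".measurements")


def save_measurements(records: Sequence[MeasurementRecord], source_path) -> Path:
    """Persist records to the sidecar next to `source_path`.

    The sidecar embeds the SHA-256 of the source file so later edits to the
    source are detectable on load.
    """
    source_path = Path(source_path)
    if not source_path.exists():
        raise DataError(f"source file not found: {source_path}")
    payload = {
        "format": SIDECAR_FORMAT,
        "version": SIDECAR_VERSION,
        "source": source_path.name,
        "source_sha256": sha256_of(source_path),
        "records": [dataclasses.asdict(r) for r in records],
    }
    out = sidecar_path(source_path)
    out.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return out


def load_measurements(source_path) -> list[MeasurementRecord]:
    """Load the sidecar for `source_path`.

    A digest mismatch (the source changed since the measurements were saved)
    emits :class:`StaleSidecarWarning` but still returns the records.
    """
    source_path = Path(source_path)
    sc = sidecar_path(source_path)
    if not sc.exists():
        raise DataError(f"no measurement sidecar for {source_path}")
    payload = json.loads(sc.read_text())
    if payload.get("format") != SIDECAR_FORMAT:
        raise DataError(f"{sc} is not a measurement sidecar")
    if source_path.exists():
        digest = sha256_of(source_path)
        if digest != payload.get("source_sha256"):
            warnings.warn(
                f"sidecar {sc.name} was saved against a different version of "
                f"{source_path.name}; measurements may be stale",
                StaleSidecarWarning,
                stacklevel=2,
            )
    return [
        MeasurementRecord(
            id=r["id"],
            kind=r["kind"],
            points=[tuple(p) for p in r["points"]],
            frame_index=r["frame_index"],
            value=r["value"],
            label=r.get("label", ""),
            color_index=r.get("color_index", 0),
        )
        for r in payload["records"]
    ]


# ---------------------------------------------------------------------------
# tabular export
# ---------------------------------------------------------------------------

_MEASUREMENT_COLUMNS = [
    "id", "kind", "frame_index", "label", "color_index",
    "n_points", "value_um", "value_mm", "value_um2", "value_mm2",
]

_CARDIAC_UM_FIELDS = [
    "edd", "esd", "av_valve_excursion",
    "oft_distal_diameter", "oft_distal_excursion", "oft_proximal_excursion",
]


def _measurement_row(r: MeasurementRecord) -> dict:
    row = {
        "id": r.id,
        "kind": r.kind,
        "frame_index": r.frame_index,
        "label": r.label,
        "color_index": r.color_index,
        "n_points": len(r.points),
        "value_um": np.nan,
        "value_mm": np.nan,
        "value_um2": np.nan,
        "value_mm2": np.nan,
    }
    if r.kind == "polygon":
        row["value_um2"] = r.value
        row["value_mm2"] = r.value * 1e-6
    else:
        row["value_um"] = r.value
        row["value_mm"] = r.value * 1e-3
    return row


def _cardiac_row(m) -> dict:
    row: dict = {}
    for name in _CARDIAC_UM_FIELDS:
        v = getattr(m, name, None)
        row[f"{name}_um"] = np.nan if v is None else v
        row[f"{name}_mm"] = np.nan if v is None else v * 1e-3
    row["sf_percent"] = m.sf
    row["heart_rate_bpm"] = m.heart_rate_bpm
    row["n_cycles_used"] = m.n_cycles_used
    return row


def _cranio_row(m) -> dict:
    row: dict = {"side": m.side}
    for name in ("meckel_length", "ceratohyal_length", "gill_length"):
        v = getattr(m, name)
        row[f"{name}_um"] = np.nan if v is None else v
        row[f"{name}_mm"] = np.nan if v is None else v * 1e-3
    for name in ("meckel_area", "ceratohyal_area"):
        v = getattr(m, name)
        row[f"{name}_um2"] = np.nan if v is None else v
        row[f"{name}_mm2"] = np.nan if v is None else v * 1e-6
    return row


def export_table(items, path, format: str = "csv") -> Path:
    """Export measurement records or metric objects as one row each.

    Lengths get paired µm and mm columns (mm = µm × 1e-3 exactly), areas get
    µm²/mm² columns. Accepts :class:`MeasurementRecord`, cardiometrics /
    craniometrics result objects, or plain dicts. ``format`` is csv or json.
    """
    if format not in ("csv", "json"):
        raise ValueError(f"unknown format {format!r}; use 'csv' or 'json'")
    items = list(items)
    rows: list[dict] = []
    for it in items:
        if isinstance(it, MeasurementRecord):
            rows.append(_measurement_row(it))
        elif hasattr(it, "sf") and hasattr(it, "edd"):
            rows.append(_cardiac_row(it))
        elif hasattr(it, "side") and hasattr(it, "meckel_length"):
            rows.append(_cranio_row(it))
        elif dataclasses.is_dataclass(it):
            rows.append(dataclasses.asdict(it))
        elif isinstance(it, dict):
            rows.append(dict(it))
        else:
            raise DataError(f"cannot export object of type {type(it).__name__}")
    if rows:
        df = pd.DataFrame(rows)
    else:
        df = pd.DataFrame(columns=_MEASUREMENT_COLUMNS)
    path = Path(path)
    if format == "csv":
        df.to_csv(path, index=False)
    else:
        df.to_json(path, orient="records", indent=2)
    return path


def export_tiff(stack, path) -> Path:
    """Write a reconstructed image stack (list of arrays or 3-D array) as TIFF."""
    import tifffile

    arrs = [np.asarray(getattr(s, "values", s), dtype=np.float32) for s in stack]
    tifffile.imwrite(Path(path), np.stack(arrs, axis=0))
    return Path(path)
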