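"""Synthetic OCT acquisitions with exhaustive ground truth.

Every test and demo in this package runs on phantoms instead of animals.
Four phantom kinds cover everything the measurement pipeline quantifies:

``reflectors``
    Point reflectors at programmed depths, emitted as raw interferometric
    fringes: per column, ``fringe(j) = dc + Σᵢ rᵢ·cos(2π·zᵢ·j/n + φᵢ) +
    noise``, with zᵢ the depth in spectral bins. The oracle for the DFT
    reconstruction chain.
``beating_heart``
    A single-ventricle rendered as an elliptical annulus of bright wall over
    a dark lumen, whose outer wall-to-wall axial diameter follows
    ``D(t) = ESD + (EDD−ESD)·(1 + cos(2π f t))/2`` with f = rate/60.
    Real traces are asymmetric; the cosine is the minimal model that exposes
    every contractually recovered quantity (EDD, ESD, SF, rate). The
    physiologic rate default sits in the 110–140 bpm band of stage 44–46
    tadpoles.
``valve``
    Two bright leaflet landmarks whose separation follows
    ``s(t) = s_max·max(0, sin(2π f t))`` — open half-cycle, sealed otherwise.
``cartilage``
    Static craniofacial shapes in the coronal plane: Meckel's bar (mid-corpus
    polyline of known length), the ceratohyal triangle (known axis length and
    area), and the anterior gill arc, with exact vertex coordinates, lengths
    (µm) and areas (µm²) recorded as ground truth.

All randomness flows from a single ``numpy`` generator seeded from the spec,
so every phantom is bit-reproducible from (spec, seed). Wall rendering uses
exact per-pixel interval-overlap coverage, so programmed sub-pixel edge
positions survive into the images and the 50 %-threshold edge detector can
recover them to a fraction of a pixel.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .container_io import AcquisitionMeta, SpectralFrame
from .errors import DataError
from .geometry import ScalingParams, polyline_length, polygon_area
from .reconstruct import StructureImage

__all__ = [
    "PhantomSpec",
    "default_meta",
    "simulate_fringes",
    "simulate_heart_movie",
    "simulate_valve_movie",
    "simulate_cartilage_frame",
    "encode_reflectivity",
    "save_ground_truth",
    "load_ground_truth",
]

PHANTOM_KINDS = ("reflectors", "beating_heart", "valve", "cartilage")

#: Rendering defaults: bright wall bands over a dim lumen give strong,
#: deterministic edges for the threshold detector.
WALL_THICKNESS_PX = 3.0
WALL_REFLECTIVITY = 1.0
LUMEN_REFLECTIVITY = 0.02


def default_meta(
    n_spectral_samples: int = 256,
    n_ascans_per_frame: int = 64,
    n_frames: int = 1,
    frame_rate: float = 100.0,
    sensitivity_mode: str = "high_speed",
) -> AcquisitionMeta:
    """Acquisition metadata for phantoms (water-immersed tadpole defaults)."""
    return AcquisitionMeta(
        n_spectral_samples=n_spectral_samples,
        n_ascans_per_frame=n_ascans_per_frame,
        n_frames=n_frames,
        frame_rate=frame_rate,
        sensitivity_mode=sensitivity_mode,
    )


@dataclass
class PhantomSpec:
    """Full description of one synthetic acquisition.

    ``geometry`` holds kind-specific parameters (see the simulate_* functions
    for keys and defaults); ``ground_truth`` is filled in by the generator
    and, together with ``meta`` and ``seed``, fully determines the noiseless
    signal.
    """

    kind: str
    geometry: dict = field(default_factory=dict)
    noise_sd: float = 0.0
    seed: int = 0
    meta: Optional[AcquisitionMeta] = None
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in PHANTOM_KINDS:
            raise ValueError(f"kind must be one of {PHANTOM_KINDS}, got {self.kind!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.kind == "beating_heart":
            edd = self.geometry.get("edd_um", 500.0)
            esd = self.geometry.get("esd_um", 325.0)
            rate = self.geometry.get("rate_bpm", 120.0)
            if not (edd > esd > 0):
                raise ValueError(f"need EDD > ESD > 0, got EDD={edd}, ESD={esd}")
            if not rate > 0:
                raise ValueError(f"rate_bpm must be > 0, got {rate}")


def _rng(spec: PhantomSpec) -> np.random.Generator:
    return np.random.default_rng(spec.seed)


def _scales(meta: AcquisitionMeta) -> ScalingParams:
    return ScalingParams.from_meta(meta)


# ---------------------------------------------------------------------------
# reflectors: raw fringes
# ---------------------------------------------------------------------------


def simulate_fringes(spec: PhantomSpec) -> SpectralFrame:
    """One raw frame of point reflectors at programmed depths.

    geometry keys: ``depths_um`` (list), ``reflectivities`` (list, default
    1.0 each), ``phases`` (list of radians, default 0.0 each), ``dc``
    (default 10.0). Depths must stay below the unambiguous half-range
    (n/2 spectral bins).
    """
    if spec.kind != "reflectors":
        raise ValueError("simulate_fringes requires kind='reflectors'")
    meta = spec.meta or default_meta()
    s = _scales(meta)
    n = meta.n_spectral_samples
    depths_um = np.atleast_1d(np.asarray(spec.geometry.get("depths_um", []), dtype=float))
    refl = np.atleast_1d(
        np.asarray(
            spec.geometry.get("reflectivities", np.ones_like(depths_um)), dtype=float
        )
    )
    phases = np.atleast_1d(
        np.asarray(spec.geometry.get("phases", np.zeros_like(depths_um)), dtype=float)
    )
    dc = float(spec.geometry.get("dc", 10.0))
    bins = depths_um / s.axial_scale
    if np.any(bins >= n / 2):
        bad = depths_um[bins >= n / 2]
        raise DataError(
            f"reflector depth(s) {bad.tolist()} µm exceed the unambiguous "
            f"range ({n // 2} bins × {s.axial_scale:.3f} µm)"
        )
    j = np.arange(n)[:, None]  # spectral sample index
    column = dc + sum(
        r * np.cos(2 * np.pi * z * j / n + phi)
        for r, z, phi in zip(refl, bins, phases)
    )
    if np.isscalar(column) or np.ndim(column) == 0:  # zero reflectors
        column = np.full((n, 1), dc)
    fringes = np.tile(column, (1, meta.n_ascans_per_frame))
    if spec.noise_sd > 0:
        fringes = fringes + _rng(spec).normal(0.0, spec.noise_sd, fringes.shape)
    spec.ground_truth = {
        "depths_um": depths_um.tolist(),
        "depth_bins": bins.tolist(),
        "reflectivities": refl.tolist(),
        "phases": phases.tolist(),
        "dc": dc,
        "axial_scale_um": s.axial_scale,
    }
    background = np.full(n, dc)
    return SpectralFrame(fringes=fringes, meta=meta, background=background)


# ---------------------------------------------------------------------------
# fringe encoding of reflectivity images
# ---------------------------------------------------------------------------


def encode_reflectivity(image: np.ndarray, meta: AcquisitionMeta, dc: float = 10.0) -> SpectralFrame:
    """Synthesize raw fringes whose DFT reconstruction returns `image`.

    Treats each depth pixel of each column as a cosine tone at an integer
    spectral bin; with no window and per-column mean subtraction the
    reconstruction recovers (n/2)·image exactly (bin orthogonality), so
    relative structure — including sub-pixel coverage values on wall edges —
    is preserved through the full fringe→image chain.
    """
    image = np.asarray(image, dtype=float)
    n = meta.n_spectral_samples
    nz = n // 2
    if image.shape[0] != nz:
        raise ValueError(f"image depth {image.shape[0]} != n/2 = {nz}")
    j = np.arange(n)[:, None]
    z = np.arange(nz)[None, :]
    cosines = np.cos(2 * np.pi * j * z / n)  # (n, nz)
    fringes = dc + cosines @ image
    return SpectralFrame(fringes=fringes, meta=meta, background=np.full(n, dc))


# ---------------------------------------------------------------------------
# beating heart
# ---------------------------------------------------------------------------


def _annulus_coverage(
    nz: int,
    nx: int,
    cz: float,
    cx: float,
    a_out_px: float,
    b_out_px: float,
    wall_px: float,
) -> np.ndarray:
    """Exact axial coverage of an elliptical wall annulus, per pixel.

    For each lateral column the annulus occupies two axial intervals
    (upper and lower wall); pixel intensity is lumen plus wall times the
    fraction of the pixel's [z−0.5, z+0.5] extent covered by wall. Exact in
    the axial direction, which is the only direction the edge detector uses.
    """
    x = np.arange(nx, dtype=float)
    u = (x - cx) / b_out_px
    outer_half = a_out_px * np.sqrt(np.clip(1.0 - u**2, 0.0, None))  # (nx,)
    a_in = max(a_out_px - wall_px, 0.0)
    b_in = max(b_out_px - wall_px, 1e-9)
    ui = (x - cx) / b_in
    inner_half = a_in * np.sqrt(np.clip(1.0 - ui**2, 0.0, None))
    inner_half = np.minimum(inner_half, outer_half)

    z = np.arange(nz, dtype=float)[:, None]
    lo_pix, hi_pix = z - 0.5, z + 0.5

    def overlap(lo_int, hi_int):
        return np.clip(np.minimum(hi_pix, hi_int) - np.maximum(lo_pix, lo_int), 0.0, 1.0)

    # upper wall [cz - outer, cz - inner], lower wall [cz + inner, cz + outer]
    cov = overlap(cz - outer_half, cz - inner_half) + overlap(cz + inner_half, cz + outer_half)
    return np.clip(cov, 0.0, 1.0)


def simulate_heart_movie(spec: PhantomSpec, as_fringes: bool = False):
    """Beating single-ventricle phantom movie.

    geometry keys and defaults: ``edd_um`` 500, ``esd_um`` 325, ``rate_bpm``
    120, ``duration_s`` 5.0, ``center_axial_px`` nz/2, ``center_lateral_px``
    nx/2, ``lateral_semi_axis_um`` 350, ``wall_thickness_px`` 3,
    ``wall_reflectivity`` 1.0, ``lumen_reflectivity`` 0.02.

    Returns ``(movie, ground_truth)`` where movie is a list of
    :class:`StructureImage` (or raw :class:`SpectralFrame` with
    ``as_fringes=True``). The programmed diameter D(t) is the
    outer-edge-to-outer-edge axial extent of the wall annulus — exactly what
    the 50 %-threshold first/last-crossing detector measures. Ground truth
    records D per frame, EDD/ESD/SF/rate, the ellipse center, and the
    recommended measurement ROI.

    The frame rate must exceed twice the beat frequency (temporal Nyquist).
    """
    if spec.kind != "beating_heart":
        raise ValueError("simulate_heart_movie requires kind='beating_heart'")
    g = spec.geometry
    edd = float(g.get("edd_um", 500.0))
    esd = float(g.get("esd_um", 325.0))
    rate = float(g.get("rate_bpm", 120.0))
    duration = float(g.get("duration_s", 5.0))
    f_hz = rate / 60.0

    meta = spec.meta or default_meta(n_frames=max(1, int(round(duration * 100.0))))
    fps = meta.frame_rate
    if fps <= 2.0 * f_hz:
        raise DataError(
            f"frame rate {fps} fps violates temporal Nyquist for {rate} bpm "
            f"(need > {2.0 * f_hz:.2f} fps)"
        )
    s = _scales(meta)
    nz = meta.n_spectral_samples // 2
    nx = meta.n_ascans_per_frame
    n_frames = int(round(duration * fps))
    meta = dataclasses.replace(meta, n_frames=n_frames)

    cz = float(g.get("center_axial_px", nz / 2.0))
    cx = float(g.get("center_lateral_px", nx / 2.0))
    b_out_px = float(g.get("lateral_semi_axis_um", 350.0)) / s.lateral_scale
    wall_px = float(g.get("wall_thickness_px", WALL_THICKNESS_PX))
    wall_r = float(g.get("wall_reflectivity", WALL_REFLECTIVITY))
    lumen_r = float(g.get("lumen_reflectivity", LUMEN_REFLECTIVITY))

    t = np.arange(n_frames) / fps
    diam = esd + (edd - esd) * (1.0 + np.cos(2.0 * np.pi * f_hz * t)) / 2.0
    if np.any(diam / 2.0 / s.axial_scale + 1 > min(cz, nz - cz)):
        raise DataError("ventricle does not fit in the depth range at EDD")

    rng = _rng(spec)
    movie = []
    for d_um in diam:
        a_out_px = (d_um / 2.0) / s.axial_scale
        cov = _annulus_coverage(nz, nx, cz, cx, a_out_px, b_out_px, wall_px)
        img = lumen_r + (wall_r - lumen_r) * cov
        if not as_fringes and spec.noise_sd > 0:
            img = np.clip(img + rng.normal(0.0, spec.noise_sd, img.shape), 0.0, None)
        movie.append(
            StructureImage(values=img, axial_scale=s.axial_scale, lateral_scale=s.lateral_scale)
        )

    half_band = 2
    roi = {
        "z_range": [0, nz],
        "x_range": [int(round(cx)) - half_band, int(round(cx)) + half_band + 1],
    }
    spec.meta = meta
    spec.ground_truth = {
        "edd_um": edd,
        "esd_um": esd,
        "sf_percent": (edd - esd) / edd * 100.0,
        "rate_bpm": rate,
        "frame_rate": fps,
        "diameters_um": diam.tolist(),
        "center_px": [cz, cx],
        "roi": roi,
        "axial_scale_um": s.axial_scale,
        "lateral_scale_um": s.lateral_scale,
    }
    if as_fringes:
        frames = []
        for img in movie:
            fr = encode_reflectivity(img.values, meta)
            if spec.noise_sd > 0:
                fr.fringes = fr.fringes + rng.normal(0.0, spec.noise_sd, fr.fringes.shape)
            frames.append(fr)
        return frames, spec.ground_truth
    return movie, spec.ground_truth


# ---------------------------------------------------------------------------
# valve
# ---------------------------------------------------------------------------


def _splat(img: np.ndarray, z: float, x: float, amplitude: float) -> None:
    """Bilinear sub-pixel splat of a bright landmark into `img` (in place)."""
    z0, x0 = int(np.floor(z)), int(np.floor(x))
    fz, fx = z - z0, x - x0
    for dz, wz in ((0, 1 - fz), (1, fz)):
        for dx, wx in ((0, 1 - fx), (1, fx)):
            zz, xx = z0 + dz, x0 + dx
            if 0 <= zz < img.shape[0] and 0 <= xx < img.shape[1]:
                img[zz, xx] += amplitude * wz * wx


def simulate_valve_movie(spec: PhantomSpec):
    """Valve-leaflet phantom: two bright landmarks opening and sealing.

    geometry keys and defaults: ``max_separation_um`` 150, ``rate_bpm`` 120,
    ``duration_s`` 5.0, ``center_axial_px`` nz/2, ``center_lateral_px`` nx/2.
    Separation follows ``s_max·max(0, sin(2π f t))`` — leaflets coincide
    during the sealed half-cycle. Returns ``(movie, ground_truth)``;
    ground truth includes per-frame leaflet trajectories (axial, lateral)
    and the separation trace in µm.
    """
    if spec.kind != "valve":
        raise ValueError("simulate_valve_movie requires kind='valve'")
    g = spec.geometry
    s_max = float(g.get("max_separation_um", 150.0))
    if not s_max > 0:
        raise ValueError(f"max_separation_um must be > 0, got {s_max}")
    rate = float(g.get("rate_bpm", 120.0))
    duration = float(g.get("duration_s", 5.0))
    f_hz = rate / 60.0
    meta = spec.meta or default_meta(n_frames=max(1, int(round(duration * 100.0))))
    fps = meta.frame_rate
    if fps <= 2.0 * f_hz:
        raise DataError(f"frame rate {fps} fps violates temporal Nyquist for {rate} bpm")
    s = _scales(meta)
    nz = meta.n_spectral_samples // 2
    nx = meta.n_ascans_per_frame
    n_frames = int(round(duration * fps))
    meta = dataclasses.replace(meta, n_frames=n_frames)
    cz = float(g.get("center_axial_px", nz / 2.0))
    cx = float(g.get("center_lateral_px", nx / 2.0))

    t = np.arange(n_frames) / fps
    sep_um = s_max * np.maximum(0.0, np.sin(2.0 * np.pi * f_hz * t))
    rng = _rng(spec)
    movie, traj = [], []
    for sep in sep_um:
        half_px = (sep / 2.0) / s.axial_scale
        p_a = (cz - half_px, cx)
        p_b = (cz + half_px, cx)
        img = np.full((nz, nx), LUMEN_REFLECTIVITY)
        _splat(img, *p_a, WALL_REFLECTIVITY)
        _splat(img, *p_b, WALL_REFLECTIVITY)
        if spec.noise_sd > 0:
            img = np.clip(img + rng.normal(0.0, spec.noise_sd, img.shape), 0.0, None)
        movie.append(
            StructureImage(values=img, axial_scale=s.axial_scale, lateral_scale=s.lateral_scale)
        )
        traj.append([list(p_a), list(p_b)])
    spec.meta = meta
    spec.ground_truth = {
        "max_separation_um": s_max,
        "rate_bpm": rate,
        "frame_rate": fps,
        "separation_um": sep_um.tolist(),
        "trajectories_px": traj,
        "axial_scale_um": s.axial_scale,
        "lateral_scale_um": s.lateral_scale,
    }
    return movie, spec.ground_truth


# ---------------------------------------------------------------------------
# cartilage
# ---------------------------------------------------------------------------


def simulate_cartilage_frame(spec: PhantomSpec):
    """Static coronal-plane cartilage phantom with exact annotations.

    Renders, at the metadata's physical scales:

    * Meckel's bar — a horizontal mid-corpus polyline of programmed length
      (``meckel_length_um``, default 400) with a rectangular outline of
      programmed width (``meckel_width_um``, default 40);
    * the ceratohyal triangle — a right triangle with a lateral leg
      (``ceratohyal_axis_um``, default 500; the midline→lateral axis) and an
      axial leg (``ceratohyal_leg_um``, default 300), closed-form area
      axis·leg/2;
    * the anterior gill arc — a quarter-circle polyline of programmed radius
      (``gill_radius_um``, default 250) sampled at ``gill_n_points``
      (default 17) vertices.

    Returns ``(StructureImage, ground_truth)`` where ground truth holds exact
    pixel vertices plus closed-form lengths (µm) and areas (µm²).
    """
    if spec.kind != "cartilage":
        raise ValueError("simulate_cartilage_frame requires kind='cartilage'")
    g = spec.geometry
    meta = spec.meta or default_meta(
        n_spectral_samples=512, n_ascans_per_frame=256, frame_rate=1.0,
        sensitivity_mode="high_sensitivity",
    )
    s = _scales(meta)
    nz = meta.n_spectral_samples // 2
    nx = meta.n_ascans_per_frame

    meckel_len = float(g.get("meckel_length_um", 400.0))
    meckel_w = float(g.get("meckel_width_um", 40.0))
    cer_axis = float(g.get("ceratohyal_axis_um", 500.0))
    cer_leg = float(g.get("ceratohyal_leg_um", 300.0))
    gill_radius = float(g.get("gill_radius_um", 250.0))
    gill_n = int(g.get("gill_n_points", 17))

    # --- Meckel's bar (anterior, horizontal) ---
    mz = float(g.get("meckel_axial_px", nz * 0.2))
    mx0 = float(g.get("meckel_lateral_px", nx * 0.1))
    mx1 = mx0 + meckel_len / s.lateral_scale
    meckel_mid = [(mz, mx0), (mz, mx1)]
    hw = (meckel_w / 2.0) / s.axial_scale
    meckel_outline = [(mz - hw, mx0), (mz - hw, mx1), (mz + hw, mx1), (mz + hw, mx0)]

    # --- ceratohyal right triangle: right angle at the midline vertex ---
    tz = float(g.get("ceratohyal_axial_px", nz * 0.5))
    tx0 = float(g.get("ceratohyal_lateral_px", nx * 0.15))
    v0 = (tz, tx0)                                       # midline vertex
    v1 = (tz, tx0 + cer_axis / s.lateral_scale)          # most lateral point
    v2 = (tz + cer_leg / s.axial_scale, tx0)             # posterior vertex
    cer_outline = [v0, v1, v2]
    cer_axis_pts = [v0, v1]

    # --- anterior gill arc: quarter circle in physical space ---
    az = float(g.get("gill_axial_px", nz * 0.75))
    ax0 = float(g.get("gill_lateral_px", nx * 0.2))
    theta = np.linspace(0.0, np.pi / 2.0, gill_n)
    gill_pts = [
        (az - gill_radius * np.sin(th) / s.axial_scale,
         ax0 + gill_radius * (1.0 - np.cos(th)) / s.lateral_scale)
        for th in theta
    ]

    for pts in (meckel_outline, cer_outline, gill_pts):
        arr = np.asarray(pts)
        if arr[:, 0].min() < 0 or arr[:, 0].max() > nz - 1 or arr[:, 1].min() < 0 or arr[:, 1].max() > nx - 1:
            raise DataError("cartilage vertices fall outside the frame")

    img = np.full((nz, nx), LUMEN_REFLECTIVITY)
    from skimage.draw import polygon as sk_polygon, line as sk_line

    rr, cc = sk_polygon(
        [p[0] for p in meckel_outline], [p[1] for p in meckel_outline], shape=img.shape
    )
    img[rr, cc] = WALL_REFLECTIVITY
    rr, cc = sk_polygon([p[0] for p in cer_outline], [p[1] for p in cer_outline], shape=img.shape)
    img[rr, cc] = WALL_REFLECTIVITY
    for (z0, x0), (z1, x1) in zip(gill_pts[:-1], gill_pts[1:]):
        rr, cc = sk_line(int(round(z0)), int(round(x0)), int(round(z1)), int(round(x1)))
        keep = (rr >= 0) & (rr < nz) & (cc >= 0) & (cc < nx)
        img[rr[keep], cc[keep]] = WALL_REFLECTIVITY

    if spec.noise_sd > 0:
        img = np.clip(img + _rng(spec).normal(0.0, spec.noise_sd, img.shape), 0.0, None)

    gill_len = polyline_length(gill_pts, s)
    spec.meta = meta
    spec.ground_truth = {
        "meckel_midcorpus_px": [list(p) for p in meckel_mid],
        "meckel_outline_px": [list(p) for p in meckel_outline],
        "meckel_length_um": meckel_len,
        "meckel_area_um2": meckel_len * meckel_w,
        "ceratohyal_axis_px": [list(p) for p in cer_axis_pts],
        "ceratohyal_outline_px": [list(p) for p in cer_outline],
        "ceratohyal_length_um": cer_axis,
        "ceratohyal_area_um2": cer_axis * cer_leg / 2.0,
        "gill_midline_px": [list(p) for p in gill_pts],
        "gill_length_um": gill_len,
        "axial_scale_um": s.axial_scale,
        "lateral_scale_um": s.lateral_scale,
        "side": "left",
    }
    frame = StructureImage(values=img, axial_scale=s.axial_scale, lateral_scale=s.lateral_scale)
    return frame, spec.ground_truth


# ---------------------------------------------------------------------------
# ground-truth sidecar
# ---------------------------------------------------------------------------


def save_ground_truth(spec: PhantomSpec, path) -> Path:
    """Persist a phantom's spec + ground truth as structured JSON."""
    payload = {
        "kind": spec.kind,
        "geometry": spec.geometry,
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
        "meta": dataclasses.asdict(spec.meta) if spec.meta is not None else None,
        "ground_truth": spec.ground_truth,
    }
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def load_ground_truth(path) -> dict:
    return json.loads(Path(path).read_text())
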