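"""Spectral-domain OCT reconstruction: fringes → structure and phase images.

Each lateral column of a raw frame is one interferometric fringe over the
spectral sample index k. Reconstruction is a column-wise discrete Fourier
transform: after optional background subtraction (stored reference spectrum
if present, else the per-column mean, which removes the zero-depth DC
artifact) and optional windowing, the DFT maps each fringe to a complex
depth profile, of which only the positive-frequency half (floor(n/2) depth
pixels) is physical. Magnitude is the structure (reflectivity) image, the
argument is the phase image, which is sensitive to sub-pixel axial motion.

Fringes are assumed already linear in wavenumber; spectral resampling and
dispersion compensation are out of scope, keeping the reconstruction a pure
DFT.

Physical scaling: axial µm/pixel is the in-air pitch divided by the
refractive index of the medium; lateral µm/pixel is the scan step. Pixels
are therefore generally anisotropic and all measurement goes through
:mod:`octmorph.geometry`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.ndimage as ndi
from scipy.signal import get_window

from .container_io import AcquisitionMeta, SpectralFrame

__all__ = [
    "ComplexImage",
    "StructureImage",
    "PhaseImage",
    "LOG_EPSILON",
    "WINDOWS",
    "dft_matrix",
    "reconstruct_frame",
    "structure_of",
    "phase_of",
    "median_filter",
    "adjust_contrast",
    "gaussian_blur",
    "crop",
    "to_uint8",
]

#: Offset added inside the log so unit magnitude maps to ~0 dB and zeros stay finite.
LOG_EPSILON = 1e-12

WINDOWS = ("none", "hann")


@dataclass
class ComplexImage:
    """Complex reconstructed image, depth pixel z (rows) × lateral pixel x."""

    values: np.ndarray
    meta: AcquisitionMeta

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        expected = self.meta.n_spectral_samples // 2
        if self.values.shape[0] != expected:
            raise ValueError(
                f"complex image must have floor(n/2)={expected} depth pixels, "
                f"got {self.values.shape[0]}"
            )


@dataclass
class StructureImage:
    """Reflectivity magnitude image with per-axis physical scaling (µm/pixel)."""

    values: np.ndarray
    axial_scale: float
    lateral_scale: float
    log_compressed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not (self.axial_scale > 0 and self.lateral_scale > 0):
            raise ValueError("scales must be positive")
        if not self.log_compressed and np.any(self.values < 0):
            raise ValueError("linear structure image must be nonnegative")


@dataclass
class PhaseImage:
    """Phase image; values in (−π, π], same scaling as the structure image."""

    values: np.ndarray
    axial_scale: float
    lateral_scale: float


def dft_matrix(n: int) -> np.ndarray:
    """The n×n DFT transform matrix, entry (j, k) = exp(−2πi·j·k/n).

    Applying it to a fringe vector gives the brute-force DFT sum. The fast
    path in :func:`reconstruct_frame` computes the same transform via FFT.
    """
    if not (isinstance(n, (int, np.integer)) and n >= 2):
        raise ValueError(f"n must be an integer >= 2, got {n!r}")
    j = np.arange(n)
    return np.exp(-2j * np.pi * np.outer(j, j) / n)


def reconstruct_frame(
    frame: SpectralFrame,
    window: str = "hann",
    subtract_background: bool = True,
) -> ComplexImage:
    """Column-wise DFT reconstruction of one raw frame.

    Per lateral column: subtract the stored background spectrum (or, absent
    one, the column mean), apply the window, transform, and keep the
    positive-frequency half. Deterministic; bit-identical for identical
    inputs.
    """
    if window not in WINDOWS:
        raise ValueError(f"unknown window {window!r}; choose from {WINDOWS}")
    n = frame.meta.n_spectral_samples
    data = frame.fringes.astype(float, copy=True)
    if subtract_background:
        if frame.background is not None:
            data -= frame.background[:, None]
        else:
            data -= data.mean(axis=0, keepdims=True)
    if window == "hann":
        data *= get_window("hann", n, fftbins=True)[:, None]
    spectrum = np.fft.fft(data, axis=0)
    return ComplexImage(values=spectrum[: n // 2, :], meta=frame.meta)


def structure_of(img: ComplexImage, log_compress: bool = False) -> StructureImage:
    """Element-wise magnitude; optionally 20·log10(|v| + ε) dB compression."""
    mag = np.abs(img.values)
    if log_compress:
        mag = 20.0 * np.log10(mag + LOG_EPSILON)
    return StructureImage(
        values=mag,
        axial_scale=img.meta.axial_pixel_pitch_medium,
        lateral_scale=img.meta.lateral_pixel_pitch,
        log_compressed=log_compress,
    )


def phase_of(img: ComplexImage) -> PhaseImage:
    """Element-wise argument in (−π, π]; the argument of 0 is defined as 0."""
    return PhaseImage(
        values=np.angle(img.values),
        axial_scale=img.meta.axial_pixel_pitch_medium,
        lateral_scale=img.meta.lateral_pixel_pitch,
    )


def _same(img: StructureImage, values: np.ndarray) -> StructureImage:
    return replace(img, values=values)


def median_filter(img: StructureImage, radius: int) -> StructureImage:
    """Square median filter of the given pixel radius; radius 0 is identity.

    Boundaries are reflected so small test images keep their edge statistics.
    """
    if radius < 0:
        raise ValueError(f"radius must be >= 0, got {radius}")
    if radius == 0:
        return _same(img, img.values.copy())
    size = 2 * int(radius) + 1
    return _same(img, ndi.median_filter(img.values, size=size, mode="reflect"))


def adjust_contrast(img: StructureImage, low_pct: float, high_pct: float) -> StructureImage:
    """Linear rescale of the [P_low, P_high] percentile range to [0, 1], clipped.

    A degenerate range (P_low == P_high, e.g. a constant image) maps
    everything to 0 — a deterministic rule rather than a divide-by-zero.
    """
    if not (0 <= low_pct < high_pct <= 100):
        raise ValueError(
            f"need 0 <= low < high <= 100, got low={low_pct}, high={high_pct}"
        )
    lo, hi = np.percentile(img.values, [low_pct, high_pct])
    if hi == lo:
        out = np.zeros_like(img.values)
    else:
        out = np.clip((img.values - lo) / (hi - lo), 0.0, 1.0)
    return StructureImage(
        values=out,
        axial_scale=img.axial_scale,
        lateral_scale=img.lateral_scale,
        log_compressed=False,
    )


def gaussian_blur(img: StructureImage, sigma: float) -> StructureImage:
    """Gaussian blur with the given sigma in pixels; sigma 0 is identity.

    Reflect boundary handling preserves interior mass without edge darkening.
    """
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return _same(img, img.values.copy())
    return _same(img, ndi.gaussian_filter(img.values, sigma=sigma, mode="reflect"))


def crop(img: StructureImage, z_range: tuple, x_range: tuple) -> StructureImage:
    """Half-open crop [z0, z1) × [x0, x1); scales are unchanged."""
    z0, z1 = z_range
    x0, x1 = x_range
    nz, nx = img.values.shape
    if not (0 <= z0 < z1 <= nz and 0 <= x0 < x1 <= nx):
        raise ValueError(
            f"crop ranges ({z0}:{z1}, {x0}:{x1}) invalid for shape {(nz, nx)}"
        )
    return _same(img, img.values[z0:z1, x0:x1].copy())


def to_uint8(img: StructureImage) -> np.ndarray:
    """8-bit view of a [0, 1] contrast-adjusted image (for PNG/TIFF export)."""
    return np.round(np.clip(img.values, 0.0, 1.0) * 255.0).astype(np.uint8)
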