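"""Cardiac quantitation: diameter traces, EDD/ESD, shortening fraction,
excursions, and heart rate.

The tadpole ventricle is measured M-mode style: within a user-chosen region
of interest, each movie frame yields one wall-to-wall axial diameter, and
the per-frame diameters form a trace over the cardiac cycle. From the trace:

* **EDD / ESD** — per-cycle maxima/minima of the diameter (end diastole /
  end systole), averaged across complete cycles; single-frame global
  extremes are also reported since a lone noisy frame can dominate them.
* **Shortening fraction** — SF = (EDD − ESD)/EDD × 100, the standard
  surrogate for ventricular pump function.
* **Excursions** — maximal leaflet separation of the atrioventricular valve
  or the outflow-tract spiral valve, taken as the maximum of a provided
  leaflet-separation trace (landmark trajectories come from annotation or
  phantom ground truth; automated leaflet tracking is out of scope).
* **Heart rate** — 60 × the dominant frequency of the mean-subtracted trace
  (hann periodogram restricted to 0.5–5 Hz, zero-padded with parabolic peak
  interpolation for sub-bin resolution).

Wall-edge detector: the axial profile averaged over the lateral ROI band is
median-smoothed, thresholded at 50 % of its maximum, and the first and last
threshold crossings — refined to sub-pixel by linear interpolation — are the
two wall edges. The wall-to-wall diameter is therefore an outer-edge to
outer-edge distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.ndimage as ndi
from scipy.signal import find_peaks, get_window

from .errors import CycleDetectionError, PeriodicityError, WallDetectionError
from .geometry import ScalingParams, point_distance

__all__ = [
    "DiameterTrace",
    "CardiacMetrics",
    "SummaryStats",
    "diameter_trace",
    "separation_trace",
    "detect_cycles",
    "compute_metrics",
    "heart_rate",
    "summarize",
]

#: Per-frame wall detectability: the ROI profile peak must stand this factor
#: above the profile median, else the frame is marked missing.
MIN_CONTRAST_RATIO = 2.0

#: Fraction of frames allowed to be missing before the trace is rejected.
MAX_MISSING_FRACTION = 0.20


@dataclass
class DiameterTrace:
    """Wall-to-wall diameter per frame (µm; NaN where walls were undetectable)."""

    values: np.ndarray
    frame_rate: float
    landmarks: Optional[np.ndarray] = None  # (n_frames, 2, 2): two (axial, lateral) points

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("trace values must be 1-D")
        if np.nanmin(self.values, initial=0.0) < 0:
            raise ValueError("diameters must be nonnegative")

    @property
    def duration_s(self) -> float:
        return len(self.values) / self.frame_rate


@dataclass
class CardiacMetrics:
    """Quantities for one tadpole/phantom; lengths µm, SF percent."""

    edd: float
    esd: float
    sf: float
    heart_rate_bpm: float
    n_cycles_used: int
    av_valve_excursion: Optional[float] = None
    oft_distal_diameter: Optional[float] = None
    oft_distal_excursion: Optional[float] = None
    oft_proximal_excursion: Optional[float] = None
    edd_global: Optional[float] = None
    esd_global: Optional[float] = None

    def __post_init__(self) -> None:
        if self.edd < self.esd:
            raise ValueError(f"EDD ({self.edd}) must be >= ESD ({self.esd})")
        if not (0.0 <= self.sf <= 100.0):
            raise ValueError(f"SF must be in [0, 100], got {self.sf}")


@dataclass
class SummaryStats:
    """Normative summary of one metric across individuals."""

    mean: float
    stdd: float
    sem: float
    cov_percent: float
    n: int


# ---------------------------------------------------------------------------
# trace extraction
# ---------------------------------------------------------------------------


def _wall_edges(profile: np.ndarray) -> Optional[tuple[float, float]]:
    """Sub-pixel first/last 50 %-threshold crossings of one axial profile."""
    prof = ndi.median_filter(profile, size=3, mode="reflect")
    peak = prof.max()
    if peak <= 0 or peak < MIN_CONTRAST_RATIO * max(np.median(prof), 1e-300):
        return None
    thr = 0.5 * peak
    above = prof >= thr
    idx = np.nonzero(above)[0]
    if idx.size == 0:
        return None
    i0, i1 = idx[0], idx[-1]
    z0 = float(i0)
    if i0 > 0 and prof[i0] > prof[i0 - 1]:
        z0 = i0 - 1 + (thr - prof[i0 - 1]) / (prof[i0] - prof[i0 - 1])
    z1 = float(i1)
    if i1 < len(prof) - 1 and prof[i1] > prof[i1 + 1]:
        z1 = i1 + (prof[i1] - thr) / (prof[i1] - prof[i1 + 1])
    return z0, z1


def diameter_trace(movie: Sequence, roi, s: ScalingParams, frame_rate: float = 1.0) -> DiameterTrace:
    """Per-frame wall-to-wall diameter within an ROI.

    `movie` is a sequence of StructureImage (or bare 2-D arrays); `roi` is
    ``((z0, z1), (x0, x1))`` — an axial search range and a lateral band whose
    columns are averaged into one profile per frame. Frames whose walls fall
    below the contrast floor become NaN; more than 20 % missing raises
    :class:`WallDetectionError`.
    """
    movie = list(movie)
    if len(movie) < 2:
        raise ValueError("movie must have at least 2 frames")
    (z0, z1), (x0, x1) = roi
    first = np.asarray(getattr(movie[0], "values", movie[0]))
    nz, nx = first.shape
    if not (0 <= z0 < z1 <= nz and 0 <= x0 < x1 <= nx):
        raise ValueError(f"ROI ({z0}:{z1}, {x0}:{x1}) outside image shape {(nz, nx)}")

    x_mid = (x0 + x1 - 1) / 2.0
    values = np.full(len(movie), np.nan)
    landmarks = np.full((len(movie), 2, 2), np.nan)
    for i, fr in enumerate(movie):
        arr = np.asarray(getattr(fr, "values", fr), dtype=float)
        profile = arr[z0:z1, x0:x1].mean(axis=1)
        edges = _wall_edges(profile)
        if edges is None:
            continue
        za, zb = z0 + edges[0], z0 + edges[1]
        landmarks[i, 0] = (za, x_mid)
        landmarks[i, 1] = (zb, x_mid)
        values[i] = point_distance((za, x_mid), (zb, x_mid), s)
    n_missing = int(np.isnan(values).sum())
    if n_missing > MAX_MISSING_FRACTION * len(movie):
        raise WallDetectionError(
            f"walls undetectable in {n_missing}/{len(movie)} frames "
            f"(> {MAX_MISSING_FRACTION:.0%} allowed); check ROI and contrast"
        )
    return DiameterTrace(values=values, frame_rate=frame_rate, landmarks=landmarks)


def separation_trace(trajectories, s: ScalingParams, frame_rate: float) -> DiameterTrace:
    """Leaflet-separation trace (µm) from per-frame landmark pairs.

    `trajectories` is (n_frames, 2, 2): two (axial, lateral) points per frame,
    e.g. phantom ground truth or manual annotation.
    """
    traj = np.asarray(trajectories, dtype=float)
    vals = np.array([point_distance(tuple(a), tuple(b), s) for a, b in traj])
    return DiameterTrace(values=vals, frame_rate=frame_rate)


# ---------------------------------------------------------------------------
# cycle detection and metrics
# ---------------------------------------------------------------------------


def _smooth_window(frame_rate: float) -> int:
    w = max(3, int(round(frame_rate / 10.0)))
    return w if w % 2 == 1 else w + 1


def _smoothed(trace: DiameterTrace) -> np.ndarray:
    """Centred moving median; preserves extrema better than a moving mean."""
    vals = trace.values.copy()
    nan = np.isnan(vals)
    if nan.any():
        vals[nan] = np.interp(np.nonzero(nan)[0], np.nonzero(~nan)[0], vals[~nan])
    return ndi.median_filter(vals, size=_smooth_window(trace.frame_rate), mode="reflect")


def detect_cycles(trace: DiameterTrace) -> list[tuple[int, int]]:
    """Complete cardiac cycles as (end_diastole_frame, end_systole_frame).

    Maxima and minima are picked on the moving-median-smoothed trace with a
    prominence floor of a quarter of the smoothed peak-to-peak range. Each
    diastolic peak followed by a systolic trough is one complete cycle; the
    reported frames are the raw-trace extrema in a smoothing-window
    neighbourhood of the smoothed peaks, so the smoothing never biases the
    extreme values themselves.
    """
    smoothed = _smoothed(trace)
    ptp = float(np.ptp(smoothed))
    if ptp <= 0:
        raise CycleDetectionError("constant trace: no cardiac cycles detectable")
    w = _smooth_window(trace.frame_rate)
    maxima, _ = find_peaks(smoothed, prominence=0.25 * ptp, distance=w)
    minima, _ = find_peaks(-smoothed, prominence=0.25 * ptp, distance=w)
    raw = trace.values
    n = len(raw)

    def _refine(idx: int, sign: float) -> int:
        lo, hi = max(idx - w, 0), min(idx + w + 1, n)
        return lo + int(np.nanargmax(sign * raw[lo:hi]))

    cycles = []
    for p in maxima:
        following = minima[minima > p]
        if following.size == 0:
            break  # trailing incomplete cycle
        q = int(following[0])
        cycles.append((_refine(int(p), +1.0), _refine(q, -1.0)))
    if len(cycles) < 2:
        raise CycleDetectionError(
            f"only {len(cycles)} complete cycle(s) found; acquire a longer "
            "movie (>= 2 full periods required)"
        )
    return cycles


def compute_metrics(
    trace: DiameterTrace,
    cycles: Sequence[tuple[int, int]],
    valve_separation_trace: Optional[DiameterTrace] = None,
    oft_distal_diameter_trace: Optional[DiameterTrace] = None,
    oft_distal_separation_trace: Optional[DiameterTrace] = None,
    oft_proximal_separation_trace: Optional[DiameterTrace] = None,
) -> CardiacMetrics:
    """Assemble CardiacMetrics from a diameter trace and detected cycles.

    EDD/ESD are the means of the per-cycle raw-trace extrema; SF is
    (EDD − ESD)/EDD × 100. Each excursion is the maximum over frames of the
    corresponding leaflet-separation trace (phantom separations peak at
    mid-systole by construction, so the global maximum is the mid-systolic
    one). The proximal outflow-tract excursion is optional — it is routinely
    left unquantified when control variability is too high.
    """
    cycles = list(cycles)
    if len(cycles) < 2:
        raise CycleDetectionError(f"need >= 2 cycles, got {len(cycles)}")
    raw = trace.values
    edd = float(np.mean([raw[ed] for ed, _ in cycles]))
    esd = float(np.mean([raw[es] for _, es in cycles]))
    if edd <= 0:
        raise ValueError("EDD is zero: shortening fraction undefined")
    sf = (edd - esd) / edd * 100.0

    def _max_of(t: Optional[DiameterTrace]) -> Optional[float]:
        return None if t is None else float(np.nanmax(t.values))

    return CardiacMetrics(
        edd=edd,
        esd=esd,
        sf=sf,
        heart_rate_bpm=heart_rate(trace),
        n_cycles_used=len(cycles),
        av_valve_excursion=_max_of(valve_separation_trace),
        oft_distal_diameter=_max_of(oft_distal_diameter_trace),
        oft_distal_excursion=_max_of(oft_distal_separation_trace),
        oft_proximal_excursion=_max_of(oft_proximal_separation_trace),
        edd_global=float(np.nanmax(raw)),
        esd_global=float(np.nanmin(raw)),
    )


# ---------------------------------------------------------------------------
# heart rate
# ---------------------------------------------------------------------------

RATE_BAND_HZ = (0.5, 5.0)
MIN_PEAK_OVER_MEDIAN = 3.0

#: Minimum fraction of the trace's total spectral power concentrated in the
#: dominant peak's main lobe. The 3×-median floor alone cannot reject
#: broadband noise (periodogram maxima have exponential tails), so a genuine
#: beat must also hold a substantial share of total power at one frequency.
MIN_PEAK_POWER_SHARE = 0.2


def heart_rate(trace: DiameterTrace) -> float:
    """Heart rate in beats/min from the dominant periodicity of the trace.

    Hann-windowed, heavily zero-padded periodogram of the mean-subtracted
    trace, restricted to 0.5–5 Hz; the peak is refined by parabolic
    interpolation on log power. Requires >= 3 s of trace and a peak at least
    3× the band's median power, else raises :class:`PeriodicityError`.
    """
    if trace.duration_s < 3.0:
        raise ValueError(f"need >= 3 s of trace, got {trace.duration_s:.2f} s")
    fs = trace.frame_rate
    x = trace.values.copy()
    nan = np.isnan(x)
    if nan.any():
        x[nan] = np.interp(np.nonzero(nan)[0], np.nonzero(~nan)[0], x[~nan])
    x = x - x.mean()
    n = len(x)
    nfft = 1 << max(13, int(math.ceil(math.log2(16 * n))))
    xw = x * get_window("hann", n)
    power = np.abs(np.fft.rfft(xw, n=nfft)) ** 2
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    band = (freqs >= RATE_BAND_HZ[0]) & (freqs <= RATE_BAND_HZ[1])
    if not band.any():
        raise PeriodicityError("frame rate too low to resolve the physiologic band")
    p_band = power[band]
    f_band = freqs[band]
    k = int(np.argmax(p_band))
    med = float(np.median(p_band))
    if med <= 0 or p_band[k] < MIN_PEAK_OVER_MEDIAN * med:
        raise PeriodicityError("no periodicity: spectral peak below 3x median band power")
    # main-lobe share of *total* power: hann lobe spans ±2 natural bins,
    # i.e. ±2·nfft/n padded bins around the peak
    lobe = int(np.ceil(2 * nfft / n))
    lobe_power = float(p_band[max(k - lobe, 0) : k + lobe + 1].sum())
    total = float(power.sum())
    if total <= 0 or lobe_power < MIN_PEAK_POWER_SHARE * total:
        raise PeriodicityError(
            "no periodicity: dominant peak holds "
            f"{lobe_power / max(total, 1e-300):.1%} of total power "
            f"(< {MIN_PEAK_POWER_SHARE:.0%})"
        )
    # parabolic refinement on log power
    f_hat = f_band[k]
    if 0 < k < len(p_band) - 1 and p_band[k - 1] > 0 and p_band[k + 1] > 0:
        y0, y1, y2 = np.log(p_band[k - 1 : k + 2])
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            delta = 0.5 * (y0 - y2) / denom
            f_hat = f_band[k] + delta * (f_band[1] - f_band[0])
    return 60.0 * float(f_hat)


# ---------------------------------------------------------------------------
# normative summaries
# ---------------------------------------------------------------------------


def summarize(values: Sequence[float]) -> SummaryStats:
    """Sample mean, SD (n−1), SEM, and CoV% of one metric across individuals."""
    vals = np.asarray(values, dtype=float)
    n = len(vals)
    if n < 2:
        raise ValueError(f"need n >= 2 values to summarize, got {n}")
    mean = float(vals.mean())
    stdd = float(vals.std(ddof=1))
    sem = stdd / math.sqrt(n)
    cov = 100.0 * stdd / mean if mean != 0 else float("nan")
    return SummaryStats(mean=mean, stdd=stdd, sem=sem, cov_percent=cov, n=n)
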