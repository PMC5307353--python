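# Methods

## Reconstruction model

A raw frame holds one real-valued fringe per lateral position, sampled at
`n` spectral points assumed already linear in wavenumber — spectral
resampling and dispersion compensation are outside this package's scope, so
reconstruction is a pure column-wise DFT. Per column: subtract the stored
reference spectrum if the frame carries one, else the column mean (removes
the zero-depth DC artifact); multiply by the window; transform; keep depth
pixels `0 … n/2 − 1` (the positive-frequency half; the negative half is its
mirror). The transform matrix `exp(−2πi·jk/n)` is exposed as
`reconstruct.dft_matrix`; the production path applies the same transform via
FFT, and tests hold the two routes together against a brute-force
direct-sum oracle at 1e−9 relative tolerance.

Numerical choices:

* **Window** — `hann` by default (periodic form), standard sidelobe control;
  `none` is retained because integer-bin phantoms reconstruct exactly
  without a window and the oracle tests use it.
* **Log compression** — `20·log10(|v| + ε)` with ε = 1e−12 in native units,
  so unit magnitude maps to ≈0 dB and zeros stay finite.
* **Phase branch** — `(−π, π]`, with `arg(0) = 0`.
* **Filters** — median/Gaussian use reflected boundaries (no edge
  darkening on small images); radius/sigma 0 are exact identities.
  Contrast adjustment rescales `[P_low, P_high]` to `[0, 1]` with clipping; a
  degenerate range (constant image) deterministically maps to 0.

## Physical scaling

The axial pixel pitch in the medium is the in-air pitch divided by the
medium's refractive index and is always derived, never stored. Defaults
describe a 1325 nm system imaging tadpoles in water: 12 µm axial pitch in
air → ≈9.02 µm in water (refractive index 1.33), 15 µm lateral pitch,
91 kHz A-scan rate in high-speed (cardiac) mode, 5.5 kHz in
high-sensitivity (craniofacial) mode.

All measurements are vertex-based in continuous 0-based pixel coordinates
(axial first), since landmarks come from interpolated edge detection or
operator clicks, not lattice cells. Distances scale each axis displacement
by its own pitch before the Euclidean combination; polygon areas use the
shoelace formula on the vertices times both pitches (vertex semantics, not
rasterized masks — this matches how an operator outlines a region).
The internal unit is µm throughout; mm appears only in exported tables
(mm = µm × 1e−3 exactly). `remeasure` always recomputes a record's value
from its points under the supplied scaling (so rescaling works); passing
`verify=True` additionally asserts 1e−9 relative agreement with the stored
value, which is the persisted-sidecar staleness check.

## Phantoms: what they emulate, and what they do not

Phantoms replace animal data in all tests. Each is bit-reproducible from
(spec, seed) through a single seeded generator.

* **Reflectors** emit fringes `dc + Σ rᵢ·cos(2π·zᵢ·j/n + φᵢ) + noise` — the
  direct oracle for the DFT chain, with programmable sub-pixel depths.
* **Beating heart** renders an elliptical annulus of bright wall
  (reflectivity 1.0, 3 px thick) over a dim lumen (0.02) whose
  outer-edge-to-outer-edge axial diameter follows
  `D(t) = ESD + (EDD−ESD)·(1 + cos 2πft)/2`, `f = rate/60`. Defaults:
  EDD 500 µm, ESD 325 µm (SF 35 %), 120 bpm — mid-physiologic for stage
  44–46 tadpoles (110–140 bpm) — 5 s at 100 fps, noiseless. Real traces are
  asymmetric in systole/diastole; only the extremes and the period are
  contractually recovered, so the cosine is the minimal adequate model. The
  generator refuses frame rates below temporal Nyquist for the programmed
  rate. Wall rendering uses exact per-pixel interval-overlap coverage
  (analytic anti-aliasing), so programmed sub-pixel edge positions survive
  into the image. A cosine-synthesis encoder turns any reflectivity image
  into fringes whose windowless reconstruction returns `(n/2)·image`
  exactly (integer-bin orthogonality), which is how the full
  fringe-to-metrics path is exercised.
* **Valve** renders two bright leaflet landmarks with separation
  `s_max·max(0, sin 2πft)` — open half-cycle, sealed otherwise — and
  reports the exact per-frame trajectories as ground truth.
* **Cartilage** renders Meckel's bar, the ceratohyal right triangle, and a
  quarter-circle gill arc with closed-form lengths/areas and exact vertex
  coordinates.

What phantoms do **not** model: speckle statistics, depth-dependent
roll-off, motion artifacts, refraction at tissue boundaries, or asymmetric
cardiac waveforms. Passing tests therefore demonstrate that the
measurement chain is correct and stable under additive noise, not that the
edge detector is robust to every property of real tissue.

## Cardiac quantitation

The wall-edge detector averages the axial profile over the lateral ROI
band, median-smooths it (3 px), thresholds at 50 % of the profile maximum,
and takes the first and last crossings, refined to sub-pixel by linear
interpolation. The measured "diameter" is therefore the outer-edge to
outer-edge extent of the wall annulus, and the phantom programs `D(t)` in
exactly that convention. A frame is marked missing when the profile peak is
below 2× the profile median; more than 20 % missing frames rejects the
trace.

Cycle detection picks maxima and minima on a centred moving-median smoothed
trace (window `max(3, frame_rate/10)` frames, odd) with a prominence floor
of ¼ of the smoothed peak-to-peak range; each diastolic peak followed by a
systolic trough is one complete cycle. The reported EDD/ESD are means of
the **raw** trace values at the per-cycle extremum frames — smoothing is
used only to locate them, never to value them, which avoids the amplitude
bias a median window would otherwise introduce (worth ≈0.5 px at 100 fps).
Global single-frame extremes are reported alongside as secondary fields.
SF is `(EDD − ESD)/EDD × 100`; excursions are maxima of supplied
leaflet-separation traces (phantom separations peak at mid-systole by
construction, so the global maximum is the mid-systolic one — a documented
simplification). The proximal outflow-tract excursion is optional and may
remain unquantified.

Heart rate is 60× the dominant frequency of the mean-subtracted trace: a
hann periodogram zero-padded to ≥16× the trace length, restricted to
0.5–5 Hz, with parabolic interpolation of the log-power peak for sub-bin
resolution (≈0.1 bpm at 5 s records). Two gates guard against
non-periodicity: the peak must exceed 3× the median in-band power, and its
main lobe must hold ≥20 % of the trace's total spectral power. The second
gate exists because periodogram maxima of broadband noise have exponential
tails — the 3×-median rule alone cannot reject white noise.

A deliberate subtlety found while validating: at the sub-pixel quantization
floor, *small* additive noise dithers the deterministic edge-coverage bias
and can slightly improve absolute SF accuracy. The noise-monotonicity test
therefore measures the median |SF deviation from the noiseless pipeline
output|, which is the actual noise response and is monotone in the noise
level.

## Craniofacial quantitation

Lengths are mid-corpus polyline lengths, areas are outline polygon areas;
everything reduces to the geometry primitives, and annotation points are
inputs (operator clicks or phantom ground truth) — automatic segmentation
is deliberately out of scope. Plane selection is modelled as the frame
maximizing mean ROI intensity, with a manual override. Measurements are
confined to one recorded side; `compare_sides` reports right/left ratios
and omits metrics missing on either side.

## Group statistics

Mann–Whitney U from mid-ranks. For pooled n ≤ 20 the two-sided p is exact:
all C(n, n_a) relabelings of the observed pooled values are enumerated
(correct under ties) and `p = min(1, 2·min(P(U ≤ u), P(U ≥ u)))`. Larger
samples use the normal approximation with tie and continuity corrections;
the method used is always reported. Group means carry t-based 95 % CIs.
Star tiers are {* p<0.05, ** p<0.01, **** p<0.0001} — deliberately no ***
tier, matching the reporting convention this package reproduces. No
multiple-testing correction is applied across metrics.

## Problem sizes

Test and acceptance runs use movies of 3–5 s at 50–100 fps with 256-sample
spectra (128 depth px × 64 lateral px frames) and cohorts of 8 per group —
large enough that every contractual tolerance (±1 px EDD, ±2 points SF,
±2 bpm) is exercised with margin, while a full suite completes in well
under a minute.

## Known limitations

* Fringes are assumed wavenumber-linear; no dispersion compensation.
* The cosine heart model cannot test diastolic/systolic asymmetry metrics.
* The wall detector assumes the two brightest in-ROI edges are the
  ventricular walls; pericardial reflections in real data would require ROI
  care by the operator.
* Valve excursions come from landmark trajectories, not automated leaflet
  tracking.
* No Doppler/flow quantities; no 3-D reslicing (the "maximal length" tilt
  adjustment is a physical-stage act, not a digital one).
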