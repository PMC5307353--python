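# octmorph

Spectral-domain OCT reconstruction and craniocardiac morphometry for
*Xenopus* tadpoles — as a library and batch CLI, with a synthetic phantom
generator replacing animal data everywhere.

## What problem this solves

Optical coherence tomography can image the beating tadpole heart and the
craniofacial cartilages *in vivo* at near-histological resolution, which
makes *Xenopus tropicalis* a fast screening model for congenital-heart-disease
and craniofacial candidate genes. Turning the instrument's raw output into
numbers requires three things this package provides:

1. **Reconstruction.** The spectrometer records an interferometric fringe
   per A-scan. Each lateral column of a raw frame is background-subtracted,
   optionally windowed, and Fourier-transformed; the positive-frequency half
   of the spectrum is the complex depth profile. Its magnitude is the
   structure (reflectivity) image, its argument the phase image.
2. **Physically scaled measurement.** Structure-image pixels are anisotropic:
   the axial pitch is the in-air pitch divided by the refractive index of the
   medium (water, 1.33), the lateral pitch is the scan step. Distances scale
   each pixel displacement by its own per-axis factor before the Euclidean
   combination; polygon areas are the pixel-space shoelace area multiplied by
   both scale factors.
3. **Quantitation.** From a cardiac movie: end-diastolic and end-systolic
   wall-to-wall diameters (EDD, ESD), the shortening fraction

   SF = (EDD − ESD)/EDD × 100,

   valve-leaflet excursions, and heart rate (periodogram of the diameter
   trace; the physiologic band is 110–140 bpm). From coronal craniofacial
   frames: Meckel's, ceratohyal, and gill cartilage lengths/areas, measured
   on one side with the other as internal control. Groups are compared with
   the exact Mann–Whitney U test and reported as means with 95 % CIs and
   significance stars.

Because live-animal acquisitions cannot ship with a software package, the
`phantom` module generates synthetic acquisitions — raw fringes or
reconstructed movies — of beating hearts, opening valves, and static
cartilages with exhaustive programmed ground truth, so every stage of the
pipeline is testable end to end.

## Worked example

Simulate a beating-heart phantom (EDD 500 µm, ESD 325 µm, 120 bpm, 3 s at
50 fps) as raw fringes, reconstruct, and quantify:

```sh
octmorph simulate --kind beating_heart --out heart.oct --duration 3 --fps 50 --seed 1
octmorph reconstruct heart.oct --out heart.tif --window none
octmorph cardiac heart.oct --out metrics.csv --window none
```

The last command logs

```
INFO octmorph: EDD=498.1 µm ESD=325.7 µm SF=34.6% rate=120.0 bpm (5 cycles)
```

and writes `metrics.csv` with paired µm/mm columns. The programmed truth was
EDD 500 µm, ESD 325 µm, SF 35 %, 120 bpm: the recovered EDD/ESD are within
one axial pixel (≈9 µm in water), SF within half a point, and the rate is
exact to 0.01 bpm. The same workflow via the library:

```python
from octmorph import phantom, cardiometrics as cm
from octmorph.geometry import ScalingParams

spec = phantom.PhantomSpec(kind="beating_heart", meta=phantom.default_meta(frame_rate=100.0))
movie, gt = phantom.simulate_heart_movie(spec)
s = ScalingParams(gt["axial_scale_um"], gt["lateral_scale_um"])
roi = (tuple(gt["roi"]["z_range"]), tuple(gt["roi"]["x_range"]))
trace = cm.diameter_trace(movie, roi, s, frame_rate=100.0)
metrics = cm.compute_metrics(trace, cm.detect_cycles(trace))
print(metrics.sf)          # 34.88  (programmed 35.0)
```

Cartilage measurement takes annotation points (phantom ground truth or a
JSON annotation file) through `octmorph cranio`, and `octmorph compare`
produces the Mann–Whitney table with 95 % CIs and star tiers {\*, \*\*,
\*\*\*\*}.

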