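"""Phantom generators: reproducibility, programmed signals, ground truth."""

import numpy as np
import pytest

from octmorph import reconstruct as rc
from octmorph.cardiometrics import compute_metrics, detect_cycles, diameter_trace
from octmorph.errors import DataError
from octmorph.geometry import ScalingParams, polygon_area, polyline_length
from octmorph.phantom import (
    PhantomSpec,
    default_meta,
    encode_reflectivity,
    simulate_cartilage_frame,
    simulate_fringes,
    simulate_heart_movie,
    simulate_valve_movie,
)

AXIAL = 12.0 / 1.33  # µm/px in water at the default metadata


def _heart_spec(edd=500.0, esd=325.0, rate=120.0, duration=5.0, fps=100.0,
                noise=0.0, seed=0):
    return PhantomSpec(
        kind="beating_heart",
        geometry={"edd_um": edd, "esd_um": esd, "rate_bpm": rate, "duration_s": duration},
        noise_sd=noise, seed=seed,
        meta=default_meta(frame_rate=fps),
    )


def _roi(gt):
    return tuple(gt["roi"]["z_range"]), tuple(gt["roi"]["x_range"])


class TestSpecValidation:
    def test_heart_requires_edd_gt_esd(self):
        with pytest.raises(ValueError, match="EDD > ESD"):
            PhantomSpec(kind="beating_heart", geometry={"edd_um": 300, "esd_um": 400})

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(kind="zebrafish")

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(kind="reflectors", noise_sd=-0.1)


class TestReflectorFringes:
    def test_single_reflector_reconstructs_at_programmed_bin(self):
        spec = PhantomSpec(kind="reflectors", geometry={"depths_um": [8 * AXIAL]},
                           meta=default_meta(n_spectral_samples=64))
        frame = simulate_fringes(spec)
        img = rc.structure_of(rc.reconstruct_frame(frame, window="none"))
        assert np.argmax(img.values[:, 0]) == 8

    def test_zero_reflectors_give_dc_only(self):
        spec = PhantomSpec(kind="reflectors", geometry={"depths_um": []},
                           meta=default_meta(n_spectral_samples=64))
        frame = simulate_fringes(spec)
        img = rc.structure_of(rc.reconstruct_frame(frame, window="none"))
        np.testing.assert_allclose(img.values, 0, atol=1e-9)

    def test_fringe_formula_matches_cosine_sum(self):
        depths = [5 * AXIAL, 13 * AXIAL]
        refl = [1.0, 0.4]
        spec = PhantomSpec(kind="reflectors",
                           geometry={"depths_um": depths, "reflectivities": refl, "dc": 3.0},
                           meta=default_meta(n_spectral_samples=64))
        frame = simulate_fringes(spec)
        n = 64
        j = np.arange(n)
        expected = 3.0 + np.cos(2 * np.pi * 5 * j / n) + 0.4 * np.cos(2 * np.pi * 13 * j / n)
        np.testing.assert_allclose(frame.fringes[:, 0], expected, atol=1e-12)

    def test_same_seed_bit_identical(self):
        kwargs = dict(kind="reflectors", geometry={"depths_um": [100.0]}, noise_sd=0.5, seed=9)
        f1 = simulate_fringes(PhantomSpec(**kwargs))
        f2 = simulate_fringes(PhantomSpec(**kwargs))
        np.testing.assert_array_equal(f1.fringes, f2.fringes)

    def test_depth_beyond_nyquist_rejected(self):
        spec = PhantomSpec(kind="reflectors", geometry={"depths_um": [40 * AXIAL]},
                           meta=default_meta(n_spectral_samples=64))
        with pytest.raises(DataError, match="unambiguous"):
            simulate_fringes(spec)

    def test_depth_sweep_recovered_within_one_pixel(self):
        """Programmed physical depth d maps to peak pixel round(d/scale) ± 1."""
        n = 256
        for d_px in np.linspace(8, 118, 10):
            d_um = d_px * AXIAL
            spec = PhantomSpec(kind="reflectors", geometry={"depths_um": [d_um]},
                               meta=default_meta(n_spectral_samples=n))
            frame = simulate_fringes(spec)
            img = rc.structure_of(rc.reconstruct_frame(frame, window="none"))
            peak = int(np.argmax(img.values[:, 0]))
            assert abs(peak - round(d_um / AXIAL)) <= 1


class TestEncodeReflectivity:
    def test_encoding_round_trips_through_reconstruction(self):
        rng = np.random.default_rng(2)
        meta = default_meta(n_spectral_samples=64, n_ascans_per_frame=8)
        image = rng.uniform(0, 1, size=(32, 8))
        image[0, :] = 0  # DC bin is consumed by background subtraction
        frame = encode_reflectivity(image, meta)
        recon = np.abs(rc.reconstruct_frame(frame, window="none").values)
        np.testing.assert_allclose(recon[1:], 32.0 * image[1:], rtol=1e-9, atol=1e-9)


class TestHeartMovie:
    def test_programmed_diameters_span_esd_to_edd(self):
        movie, gt = simulate_heart_movie(_heart_spec())
        d = np.array(gt["diameters_um"])
        assert d.min() == pytest.approx(325.0, abs=1e-6)
        assert d.max() == pytest.approx(500.0, abs=1e-6)
        assert len(movie) == len(d) == 500

    def test_degenerate_equal_diameters_is_static(self):
        spec = PhantomSpec(
            kind="beating_heart",
            geometry={"edd_um": 400.0, "esd_um": 400.0 - 1e-9, "rate_bpm": 120,
                      "duration_s": 1.0},
            meta=default_meta(frame_rate=50.0),
        )
        movie, _ = simulate_heart_movie(spec)
        for img in movie[1:]:
            np.testing.assert_allclose(img.values, movie[0].values, atol=1e-9)

    def test_nyquist_violation_rejected(self):
        spec = _heart_spec(rate=140.0, fps=4.0)
        with pytest.raises(DataError, match="Nyquist"):
            simulate_heart_movie(spec)

    def test_determinism_with_noise(self):
        m1, _ = simulate_heart_movie(_heart_spec(noise=0.05, seed=4, duration=1.0, fps=50))
        m2, _ = simulate_heart_movie(_heart_spec(noise=0.05, seed=4, duration=1.0, fps=50))
        for a, b in zip(m1, m2):
            np.testing.assert_array_equal(a.values, b.values)

    def test_noiseless_recovery_of_sf(self):
        """End-to-end: phantom → trace → metrics recovers SF 35 ± 2 points."""
        movie, gt = simulate_heart_movie(_heart_spec())
        s = ScalingParams(gt["axial_scale_um"], gt["lateral_scale_um"])
        trace = diameter_trace(movie, _roi(gt), s, frame_rate=gt["frame_rate"])
        metrics = compute_metrics(trace, detect_cycles(trace))
        assert metrics.sf == pytest.approx(35.0, abs=2.0)

    def test_fringe_encoded_movie_matches_structure_movie(self):
        spec = _heart_spec(duration=0.5, fps=50.0)
        movie, _ = simulate_heart_movie(spec)
        spec2 = _heart_spec(duration=0.5, fps=50.0)
        frames, _ = simulate_heart_movie(spec2, as_fringes=True)
        recon = np.abs(rc.reconstruct_frame(frames[0], window="none").values)
        np.testing.assert_allclose(recon[1:] / 128.0, movie[0].values[1:], rtol=1e-8, atol=1e-8)


class TestValveMovie:
    def test_programmed_max_separation_recovered(self):
        spec = PhantomSpec(kind="valve", geometry={"max_separation_um": 150.0},
                           meta=default_meta(frame_rate=100.0))
        _, gt = simulate_valve_movie(spec)
        sep = np.array(gt["separation_um"])
        # temporal sampling bound: s_max·(1 − cos(π·f/fps)) ≈ 0.30 µm here
        assert sep.max() == pytest.approx(150.0, abs=0.5)

    def test_closed_phase_separation_zero(self):
        spec = PhantomSpec(kind="valve", geometry={"max_separation_um": 100.0,
                                                   "rate_bpm": 120, "duration_s": 1.0},
                           meta=default_meta(frame_rate=100.0))
        _, gt = simulate_valve_movie(spec)
        sep = np.array(gt["separation_um"])
        t = np.arange(len(sep)) / 100.0
        closed = np.sin(2 * np.pi * 2.0 * t) < -1e-9
        np.testing.assert_array_equal(sep[closed], 0.0)

    def test_determinism(self):
        spec_kwargs = dict(kind="valve", geometry={"max_separation_um": 80.0,
                                                   "duration_s": 1.0},
                           noise_sd=0.02, seed=3)
        m1, _ = simulate_valve_movie(PhantomSpec(meta=default_meta(frame_rate=50.0), **spec_kwargs))
        m2, _ = simulate_valve_movie(PhantomSpec(meta=default_meta(frame_rate=50.0), **spec_kwargs))
        for a, b in zip(m1, m2):
            np.testing.assert_array_equal(a.values, b.values)


class TestCartilageFrame:
    def test_meckel_bar_closed_forms(self):
        frame, gt = simulate_cartilage_frame(PhantomSpec(kind="cartilage"))
        s = ScalingParams(gt["axial_scale_um"], gt["lateral_scale_um"])
        assert polyline_length(gt["meckel_midcorpus_px"], s) == pytest.approx(
            gt["meckel_length_um"], rel=1e-12)
        assert polygon_area(gt["meckel_outline_px"], s) == pytest.approx(
            gt["meckel_area_um2"], rel=1e-12)

    def test_345_right_triangle_area(self):
        spec = PhantomSpec(kind="cartilage",
                           geometry={"ceratohyal_axis_um": 400.0, "ceratohyal_leg_um": 300.0})
        _, gt = simulate_cartilage_frame(spec)
        assert gt["ceratohyal_area_um2"] == pytest.approx(60_000.0)
        s = ScalingParams(gt["axial_scale_um"], gt["lateral_scale_um"])
        assert polygon_area(gt["ceratohyal_outline_px"], s) == pytest.approx(60_000.0, rel=1e-12)
        # hypotenuse of the 3-4-5 triangle in physical space
        v1, v2 = gt["ceratohyal_outline_px"][1], gt["ceratohyal_outline_px"][2]
        from octmorph.geometry import point_distance
        assert point_distance(tuple(v1), tuple(v2), s) == pytest.approx(500.0, rel=1e-12)

    def test_anisotropic_scales_same_physical_truth(self):
        """Physical ground truth is scale-independent: re-render at 9/15 µm
        pitches and at unit pitches — same µm/µm² answers."""
        from octmorph.container_io import AcquisitionMeta

        iso_meta = AcquisitionMeta(
            n_spectral_samples=1400, n_ascans_per_frame=700, n_frames=1,
            frame_rate=1.0, axial_pixel_pitch_air=1.33, lateral_pixel_pitch=1.0,
        )
        _, gt_aniso = simulate_cartilage_frame(PhantomSpec(kind="cartilage"))
        _, gt_iso = simulate_cartilage_frame(PhantomSpec(kind="cartilage", meta=iso_meta))
        for key in ("meckel_length_um", "meckel_area_um2", "ceratohyal_length_um",
                    "ceratohyal_area_um2", "gill_length_um"):
            assert gt_aniso[key] == pytest.approx(gt_iso[key], rel=1e-9)

    def test_rendered_shapes_are_bright(self):
        frame, gt = simulate_cartilage_frame(PhantomSpec(kind="cartilage"))
        z, x = gt["meckel_midcorpus_px"][0]
        assert frame.values[int(round(z)), int(round(x)) + 2] == pytest.approx(1.0)


class TestNoiseLadder:
    def test_noise_degrades_sf_precision_monotonically(self):
        """Median |SF deviation from the noiseless recovery| is non-decreasing
        in detector noise (3-level ladder, 20 seeded replicates each).

        Deviation is measured against the noiseless pipeline output rather
        than the programmed SF: tiny noise dithers the deterministic
        sub-pixel quantization bias, so absolute accuracy is not monotone
        near the quantization floor, while the noise response itself is.
        """
        spec0 = _heart_spec(duration=3.0, fps=50.0, noise=0.0)
        movie, gt = simulate_heart_movie(spec0)
        s = ScalingParams(gt["axial_scale_um"], gt["lateral_scale_um"])
        trace0 = diameter_trace(movie, _roi(gt), s, frame_rate=50.0)
        sf0 = compute_metrics(trace0, detect_cycles(trace0)).sf

        medians = []
        for lvl in (0.0, 0.1, 0.3):
            devs = []
            for rep in range(20):
                spec = _heart_spec(duration=3.0, fps=50.0, noise=lvl, seed=100 + rep)
                movie, gt = simulate_heart_movie(spec)
                trace = diameter_trace(movie, _roi(gt), s, frame_rate=50.0)
                m = compute_metrics(trace, detect_cycles(trace))
                devs.append(abs(m.sf - sf0))
            medians.append(float(np.median(devs)))
        assert medians[0] <= medians[1] + 1e-9
        assert medians[1] <= medians[2] + 1e-9
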