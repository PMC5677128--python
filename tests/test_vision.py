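"""Tests for luminance, granularity/KL and receptor-noise-limited JND."""

import math

import numpy as np
import pytest

from mimicrylab.vision import (
    GranularitySpectrum,
    HyperspectralCube,
    JNDResult,
    ReceptorModel,
    granularity_spectrum,
    jnd_map,
    jnd_summary,
    kl_divergence,
    luminance_map,
    percent_luminance_change,
    quantum_catches,
    read_cube,
    read_mask,
    write_cube,
    write_mask,
)
from mimicrylab.vision import _rnl_distance
from mimicrylab.synth import SceneSpec, generate_scene


WL16 = np.linspace(360, 660, 16)


def uniform_cube(value, h=8, w=8, b=16):
    return HyperspectralCube(np.full((h, w, b), float(value)), WL16)


class TestLuminance:
    def test_uniform_cube(self):
        cube = uniform_cube(2.5)
        np.testing.assert_allclose(luminance_map(cube), 16 * 2.5)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        cube = HyperspectralCube(rng.random((6, 6, 16)), WL16)
        doubled = HyperspectralCube(2 * cube.radiance, WL16)
        np.testing.assert_allclose(luminance_map(doubled), 2 * luminance_map(cube))

    def test_percent_change_trivia(self):
        cube = uniform_cube(1.0)
        mask = np.zeros((8, 8), dtype=bool)
        mask[2:5, 2:5] = True
        mean, sd = percent_luminance_change(cube, mask)
        assert mean == pytest.approx(0.0, abs=1e-12)
        assert sd == pytest.approx(0.0, abs=1e-12)
        bright = cube.radiance.copy()
        bright[mask] *= 2
        mean2, _ = percent_luminance_change(HyperspectralCube(bright, WL16), mask)
        assert mean2 == pytest.approx(100.0, abs=1e-9)

    def test_generator_truth_recovered_noiseless(self):
        spec = SceneSpec(texture_amplitude=0.0, butterfly_scale=1.37, seed=0)
        cube, mask, truth = generate_scene(spec)
        mean, sd = percent_luminance_change(cube, mask)
        assert mean == pytest.approx(truth.percent_luminance_change, abs=1e-9)
        assert sd == pytest.approx(0.0, abs=1e-9)


class TestGranularity:
    def test_identical_content_identical_spectra(self):
        rng = np.random.default_rng(1)
        tile = rng.random((16, 32))
        img = np.vstack([tile, tile])
        top = np.zeros((32, 32), dtype=bool)
        top[:16] = True
        g1 = granularity_spectrum(img, top)
        g2 = granularity_spectrum(img, ~top)
        np.testing.assert_allclose(g1.energies, g2.energies, atol=1e-12)

    def test_constant_region_degenerate_uniform(self):
        img = np.ones((16, 16))
        mask = np.zeros((16, 16), dtype=bool)
        mask[4:10, 4:10] = True
        g = granularity_spectrum(img, mask)
        assert g.degenerate
        np.testing.assert_allclose(g.energies, 1 / 7)

    def test_energies_sum_to_one(self):
        rng = np.random.default_rng(2)
        img = rng.random((24, 24))
        mask = np.zeros((24, 24), dtype=bool)
        mask[3:20, 5:18] = True
        g = granularity_spectrum(img, mask)
        assert g.energies.sum() == pytest.approx(1.0, abs=1e-9)
        assert (g.energies >= 0).all()

    def test_sinusoid_lands_in_containing_band(self):
        h = w = 64
        _, xx = np.mgrid[0:h, 0:w]
        freq = 8 / w  # integer number of cycles: no spectral leakage
        img = np.sin(2 * np.pi * freq * xx)
        mask = np.ones((h, w), dtype=bool)
        mask[0, 0] = False  # keep a non-empty complement
        g = granularity_spectrum(img, mask)
        band = np.searchsorted(g.band_edges, freq, side="right") - 1
        assert g.energies[band] >= 0.95


class TestKL:
    def make(self, energies):
        e = np.asarray(energies, float)
        return GranularitySpectrum(e / e.sum(), np.linspace(0, 0.5, e.size + 1))

    def test_zero_iff_equal(self):
        p = self.make([0.4, 0.3, 0.2, 0.1])
        assert kl_divergence(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_asymmetry(self):
        p = self.make([0.7, 0.1, 0.1, 0.1])
        q = self.make([0.25, 0.25, 0.25, 0.25])
        assert kl_divergence(p, q) != pytest.approx(kl_divergence(q, p), abs=1e-6)
        assert kl_divergence(p, q) >= 0 and kl_divergence(q, p) >= 0

    def test_hand_computed_value(self):
        p = self.make([0.9, 0.1])
        q = self.make([0.5, 0.5])
        expected = 0.9 * math.log(1.8) + 0.1 * math.log(0.2)
        assert kl_divergence(p, q) == pytest.approx(expected, abs=1e-6)

    def test_mismatched_bands_rejected(self):
        p = self.make([0.5, 0.5])
        q = self.make([0.3, 0.3, 0.4])
        with pytest.raises(ValueError):
            kl_divergence(p, q)


class TestQuantumCatches:
    def test_concentrated_sensitivity(self):
        sens = np.zeros((1, 16))
        sens[0, 5] = 1.0
        rec = ReceptorModel(sens, [1.0])
        spectrum = np.arange(16.0)
        q = quantum_catches(spectrum, rec, WL16)
        dl = np.gradient(WL16)
        assert q[0] == pytest.approx(spectrum[5] * dl[5])

    def test_linearity(self):
        rec = ReceptorModel.tetrachromat(WL16)
        rng = np.random.default_rng(3)
        s = rng.random(16)
        np.testing.assert_allclose(
            quantum_catches(2 * s, rec, WL16), 2 * quantum_catches(s, rec, WL16)
        )

    def test_flat_spectrum_gives_sensitivity_integrals(self):
        rec = ReceptorModel.trichromat(WL16)
        q = quantum_catches(np.ones(16), rec, WL16)
        dl = np.gradient(WL16)
        np.testing.assert_allclose(q, (rec.sensitivities * dl).sum(axis=1))


class TestJND:
    def test_background_matched_pixel_zero(self):
        spec = SceneSpec(texture_amplitude=0.0, butterfly_scale=1.0, seed=0)
        cube, mask, _ = generate_scene(spec)
        rec = ReceptorModel.tetrachromat(cube.wavelengths)
        res = jnd_map(cube, mask, rec)
        assert res.mean == pytest.approx(0.0, abs=1e-9)
        assert res.n_excluded == 0

    def test_illumination_scaling_invariance(self):
        spec = SceneSpec(
            texture_amplitude=0.15,
            butterfly_spectrum=tuple(np.linspace(0.4, 1.2, 16)),
            seed=4,
        )
        cube, mask, _ = generate_scene(spec)
        rec = ReceptorModel.tetrachromat(cube.wavelengths)
        r1 = jnd_map(cube, mask, rec)
        scaled = HyperspectralCube(cube.radiance * 11.7, cube.wavelengths)
        r2 = jnd_map(scaled, mask, rec)
        assert np.nanmax(np.abs(r1.jnd - r2.jnd)) < 1e-10

    def test_dichromat_closed_form(self):
        rng = np.random.default_rng(5)
        df = rng.normal(size=(500, 2))
        noise = np.array([0.05, 0.13])
        general = _rnl_distance(df, noise)
        closed = np.abs(df[:, 0] - df[:, 1]) / math.sqrt((noise**2).sum())
        assert np.max(np.abs(general - closed)) < 1e-10

    def test_tetrachromat_formula_structure(self):
        """4-class quadratic form matches an explicit expansion."""
        rng = np.random.default_rng(6)
        df = rng.normal(size=4)
        e = np.array([0.1, 0.07, 0.06, 0.05])
        num = (
            (e[2] * e[3]) ** 2 * (df[0] - df[1]) ** 2
            + (e[1] * e[3]) ** 2 * (df[0] - df[2]) ** 2
            + (e[1] * e[2]) ** 2 * (df[0] - df[3]) ** 2
            + (e[0] * e[3]) ** 2 * (df[1] - df[2]) ** 2
            + (e[0] * e[2]) ** 2 * (df[1] - df[3]) ** 2
            + (e[0] * e[1]) ** 2 * (df[2] - df[3]) ** 2
        )
        den = (
            (e[0] * e[1] * e[2]) ** 2
            + (e[0] * e[1] * e[3]) ** 2
            + (e[0] * e[2] * e[3]) ** 2
            + (e[1] * e[2] * e[3]) ** 2
        )
        expected = math.sqrt(num / den)
        assert _rnl_distance(df[None, :], e)[0] == pytest.approx(expected, rel=1e-12)

    def test_zero_catch_pixels_excluded(self):
        spec = SceneSpec(texture_amplitude=0.0, butterfly_scale=1.0, seed=0)
        cube, mask, _ = generate_scene(spec)
        radiance = cube.radiance.copy()
        ys, xs = np.nonzero(mask)
        radiance[ys[0], xs[0], :] = 0.0  # dead pixel
        res = jnd_map(
            HyperspectralCube(radiance, cube.wavelengths),
            mask,
            ReceptorModel.tetrachromat(cube.wavelengths),
        )
        assert res.n_excluded == 1
        assert np.isnan(res.jnd[ys[0], xs[0]])


class TestJNDSummary:
    def make_result(self, values):
        h = w = 20
        mask = np.zeros((h, w), dtype=bool)
        mask.ravel()[: len(values)] = True
        jnd = np.full((h, w), np.nan)
        jnd[mask] = values
        return JNDResult(jnd, mask, float(np.mean(values)), float(np.std(values)), 0)

    def test_constant_map_zero_sd(self):
        s = jnd_summary(self.make_result(np.full(50, 2.0)))
        assert s["sd"] == 0.0

    def test_histogram_normalized(self):
        rng = np.random.default_rng(7)
        s = jnd_summary(self.make_result(rng.lognormal(0, 1, 200)))
        assert s["density"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_bimodal_field_shows_two_modes(self):
        values = np.concatenate([np.full(150, 0.1), np.full(150, 5.0)])
        s = jnd_summary(self.make_result(values), n_bins=20)
        occupied = np.nonzero(s["density"] > 0)[0]
        assert occupied.size == 2
        lo, hi = s["bin_edges"][occupied], s["bin_edges"][occupied + 1]
        assert lo[0] <= 0.1 <= hi[0] * 1.0001
        assert lo[1] <= 5.0 <= hi[1] * 1.0001


class TestCubeIO:
    def test_round_trip(self, tmp_path):
        spec = SceneSpec(height=16, width=16, texture_amplitude=0.2, seed=8)
        cube, mask, _ = generate_scene(spec)
        p = tmp_path / "scene.cube"
        write_cube(cube, p)
        back = read_cube(p)
        np.testing.assert_allclose(back.radiance, cube.radiance, atol=1e-6)
        np.testing.assert_allclose(back.wavelengths, cube.wavelengths)
        mp = tmp_path / "mask.txt"
        write_mask(mask, mp)
        np.testing.assert_array_equal(read_mask(mp), mask)

    def test_receptor_json_round_trip(self, tmp_path):
        rec = ReceptorModel.tetrachromat(WL16)
        p = tmp_path / "rec.json"
        rec.to_json(p, WL16)
        back = ReceptorModel.from_json(p)
        np.testing.assert_allclose(back.sensitivities, rec.sensitivities)
        np.testing.assert_allclose(back.noise, rec.noise)
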