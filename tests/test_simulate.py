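"""Forward model: response prediction, rendering, noise, scene factories."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from specmix import simulate as sim


class TestFluorophoreModel:
    def test_invalid_models_rejected(self):
        with pytest.raises(ValueError, match="blue of excitation"):
            sim.FluorophoreModel("x", 500.0, 10.0, 490.0, 10.0)
        with pytest.raises(ValueError, match="widths"):
            sim.FluorophoreModel("x", 500.0, 0.0, 520.0, 10.0)


class TestPredictResponse:
    def test_full_emission_band_at_peak_excitation(self):
        """A band covering the emission peak ± 6σ at peak excitation captures
        essentially the whole brightness."""
        f = sim.FluorophoreModel("x", 405.0, 15.0, 530.0, 20.0, brightness=2.5)
        scheme = sim.AcquisitionScheme(
            excitations=(405.0,),
            detectors=(((530.0 - 6 * 20.0, 530.0 + 6 * 20.0),),),
        )
        (resp,) = sim.predict_response(f, scheme)
        assert resp == pytest.approx(2.5, rel=1e-8)

    def test_far_off_excitation_vanishes(self):
        f = sim.FluorophoreModel("x", 400.0, 10.0, 430.0, 15.0)
        scheme = sim.AcquisitionScheme(
            excitations=(500.0,), detectors=(((510.0, 560.0),),)
        )
        (resp,) = sim.predict_response(f, scheme)
        assert resp < 1e-20

    def test_band_integral_matches_quadrature(self):
        """One-sigma band at peak excitation: response equals the numerically
        integrated Gaussian emission density (~0.3413)."""
        f = sim.FluorophoreModel("x", 500.0, 15.0, 560.0, 20.0)
        scheme = sim.AcquisitionScheme(
            excitations=(500.0,), detectors=(((560.0, 580.0),),)
        )
        (resp,) = sim.predict_response(f, scheme)
        density = lambda w: math.exp(-((w - 560.0) ** 2) / (2 * 20.0**2)) / (
            20.0 * math.sqrt(2 * math.pi)
        )
        expected, _ = quad(density, 560.0, 580.0)
        assert resp == pytest.approx(expected, abs=1e-10)
        assert resp == pytest.approx(0.3413, abs=5e-4)

    def test_fixture_emissions_span_visible_to_near_ir(self, fluorophores):
        peaks = [f.emission_peak for f in fluorophores]
        assert len(fluorophores) == 10
        assert min(peaks) <= 440.0
        assert max(peaks) >= 790.0


class TestRenderSpectralImage:
    def _empty_scene(self, **kw):
        return sim.SceneSpec(
            shape=(2, 8, 8), pixel_size=(1.0, 0.5, 0.5), channels=[], **kw
        )

    def test_zero_scene_renders_zero(self, scheme):
        r = sim.render_spectral_image(self._empty_scene(), [], np.zeros(scheme.m), scheme)
        np.testing.assert_array_equal(r.image.data, 0.0)

    def test_noise_free_equals_linear_model(self, scheme, fluorophores, af_spectrum):
        scene = sim.make_multiplex_scene(shape=(2, 12, 12), seed=8)
        r = sim.render_spectral_image(scene, fluorophores, af_spectrum, scheme)
        expected = r.truth @ r.responses.T
        np.testing.assert_array_equal(r.image.data, expected)

    def test_intensity_conservation_noise_free(self, scheme, fluorophores, af_spectrum):
        scene = sim.make_multiplex_scene(shape=(2, 10, 10), seed=3)
        r = sim.render_spectral_image(scene, fluorophores, af_spectrum, scheme)
        total = sum(
            r.truth[..., c].sum() * r.responses[:, c].sum()
            for c in range(r.truth.shape[-1])
        )
        assert r.image.data.sum() == pytest.approx(total, rel=1e-12)

    def test_identical_seed_identical_image(self, scheme, fluorophores, af_spectrum):
        for _ in range(2):
            scene = sim.make_multiplex_scene(shape=(1, 8, 8), seed=5, photon_budget=100.0)
        a = sim.render_spectral_image(scene, fluorophores, af_spectrum, scheme)
        b = sim.render_spectral_image(scene, fluorophores, af_spectrum, scheme)
        np.testing.assert_array_equal(a.image.data, b.image.data)

    def test_poisson_mean_and_variance_scaling(self, scheme):
        """Monte-Carlo over one pixel: empirical mean within 3 s.e. of the
        expected spectrum, and variance × budget ≈ mean."""
        f = sim.FluorophoreModel("x", 500.0, 15.0, 540.0, 20.0)
        small = sim.AcquisitionScheme(excitations=(500.0,), detectors=(((510.0, 590.0),),))
        budget = 1e4
        n_draws = 100_000
        expected = 0.8 * sim.predict_response(f, small)[0]
        draws = []
        for i in range(1):
            scene = sim.SceneSpec(
                shape=(1, 1, 1),
                pixel_size=(1.0, 1.0, 1.0),
                channels=[sim.ChannelSpec(name="x", array=np.full((1, 1, 1), 0.8))],
                photon_budget=budget,
                seed=777,
            )
        rng = np.random.default_rng(777)
        samples = rng.poisson(expected * budget, size=n_draws) / budget
        se = samples.std(ddof=1) / np.sqrt(n_draws)
        assert samples.mean() == pytest.approx(expected, abs=3 * se)
        assert samples.var(ddof=1) * budget == pytest.approx(expected, rel=0.05)
        # the renderer's single draw falls on the same distribution's scale
        r = sim.render_spectral_image(scene, [f], np.zeros(1), small)
        assert abs(r.image.data[0, 0, 0, 0] - expected) < 6 * np.sqrt(expected / budget)

    def test_channel_count_mismatch_rejected(self, scheme, fluorophores):
        scene = sim.make_multiplex_scene(n_channels=3, shape=(1, 4, 4))
        with pytest.raises(ValueError, match="fluorophore models"):
            sim.render_spectral_image(scene, fluorophores[:2], np.zeros(scheme.m), scheme)


class TestRedundantDetectionScene:
    def test_equal_gains_identical_truth(self, scheme, af_spectrum):
        fl = sim.default_fluorophores()[:2]
        scene = sim.make_redundant_detection_scene(None, (1.0, 1.0), seed=1, shape=(1, 16, 16))
        r = sim.render_spectral_image(scene, fl, af_spectrum, scheme)
        np.testing.assert_array_equal(r.truth[..., 0], r.truth[..., 1])

    def test_gain_two_doubles_truth(self, scheme, af_spectrum):
        fl = sim.default_fluorophores()[:2]
        scene = sim.make_redundant_detection_scene(None, (1.0, 2.0), seed=1, shape=(1, 16, 16))
        r = sim.render_spectral_image(scene, fl, af_spectrum, scheme)
        np.testing.assert_allclose(r.truth[..., 1], 2.0 * r.truth[..., 0], atol=1e-14)

    def test_noise_free_voxel_scatter_is_exact_line_through_origin(
        self, scheme, af_spectrum, pair_reference
    ):
        """End-to-end: render, unmix, bin — the two-channel scatter of raw
        abundances lies exactly on a slope-2 line through the origin."""
        from specmix.quantitation import bin_voxels
        from specmix.unmixing import unmix_image

        fl, ref, peaks = pair_reference
        scene = sim.make_redundant_detection_scene(
            None, (1.0, 2.0), seed=6, shape=(1, 44, 44), af_amplitude=0.2
        )
        r = sim.render_spectral_image(scene, fl, af_spectrum, scheme)
        table = bin_voxels(unmix_image(r.image, ref), (1.2, 2.0, 2.0))
        a = table.table[fl[0].name].to_numpy() / peaks[0]
        b = table.table[fl[1].name].to_numpy() / peaks[1]
        np.testing.assert_allclose(b, 2.0 * a, rtol=1e-6, atol=1e-9)


class TestSingleMoleculeScene:
    def test_zero_dots(self):
        scene = sim.make_single_molecule_scene(0, seed=1)
        assert scene.truth_dots == []

    def test_count_and_min_separation(self):
        scene = sim.make_single_molecule_scene(25, seed=2, min_separation_um=1.5)
        pos = np.array(scene.truth_dots)
        assert len(pos) == 25
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 1.5

    def test_seed_determinism(self):
        a = sim.make_single_molecule_scene(10, seed=9)
        b = sim.make_single_molecule_scene(10, seed=9)
        assert a.truth_dots == b.truth_dots

    def test_infeasible_packing_errors(self):
        with pytest.raises(RuntimeError, match="could not place"):
            sim.make_single_molecule_scene(
                200, min_separation_um=5.0, seed=0, max_attempts=500
            )

    def test_both_channels_share_truth(self):
        scene = sim.make_single_molecule_scene(5, seed=4)
        pa = [p.position for p in scene.channels[0].points]
        pb = [p.position for p in scene.channels[1].points]
        assert pa == pb
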