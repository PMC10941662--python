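"""Acquisition schemes, reference-spectrum extraction, AF placement, conditioning."""

import numpy as np
import pytest

from specmix import simulate as sim
from specmix.spectra import (
    AcquisitionScheme,
    EEMScan,
    ReferenceMatrix,
    ReferenceSpectrum,
    SchemeError,
    condition_report,
    extract_reference_spectrum,
    optimize_af_channel,
)


class TestAcquisitionScheme:
    def test_default_fixture_geometry(self, scheme):
        assert len(scheme.excitations) == 11
        assert scheme.m == 26
        assert all(1 <= len(b) <= 4 for b in scheme.detectors)
        assert scheme.m == sum(len(b) for b in scheme.detectors)

    @pytest.mark.parametrize(
        "excitations, detectors, message",
        [
            ((500.0, 450.0), (((510, 540),), ((460, 490),)), "strictly increasing"),
            ((450.0,), (((440, 470),),), "blue of excitation"),
            ((450.0,), (((470, 460),),), "start >= end"),
            ((450.0,), ((tuple((460 + i, 461 + i) for i in range(5))),), "1-4 allowed"),
        ],
    )
    def test_invalid_schemes_rejected(self, excitations, detectors, message):
        with pytest.raises(SchemeError, match=message):
            AcquisitionScheme(excitations=excitations, detectors=detectors)


class TestReferenceSpectrum:
    def test_normalized_to_unit_peak(self, scheme):
        v = np.linspace(0.1, 7.0, scheme.m)
        s = ReferenceSpectrum("c", v, scheme)
        assert s.intensities.max() == 1.0
        np.testing.assert_allclose(s.intensities, v / v.max())

    def test_all_zero_rejected(self, scheme):
        with pytest.raises(ValueError, match="all-zero"):
            ReferenceSpectrum("c", np.zeros(scheme.m), scheme)

    def test_wrong_length_rejected(self, scheme):
        with pytest.raises(SchemeError):
            ReferenceSpectrum("c", np.ones(scheme.m + 1), scheme)


class TestExtractReferenceSpectrum:
    def test_homogeneous_image_selection_irrelevant(self, scheme):
        s = np.linspace(1.0, 2.0, scheme.m)
        img = np.tile(s, (1, 8, 8, 1))
        out = extract_reference_spectrum(img, scheme)
        np.testing.assert_allclose(out.intensities, s / s.max())

    def test_default_quantile_picks_bright_minority(self, scheme):
        """99% dim pixels with spectrum a, 1% bright with 10*b: the default
        top-0.1% selection must recover b — verified against a brute-force
        selection of the brightest pixels."""
        rng = np.random.default_rng(42)
        a = rng.uniform(0.1, 1.0, scheme.m)
        b = rng.uniform(0.1, 1.0, scheme.m)
        n = 10_000
        flat = np.tile(a, (n, 1))
        bright = rng.choice(n, size=100, replace=False)
        flat[bright] = 10.0 * b
        img = flat.reshape(1, 100, 100, scheme.m)
        out = extract_reference_spectrum(img, scheme, quantile=0.001)
        # oracle: brute-force brightest ceil(0.001*n) pixels, mean, normalize
        totals = flat.sum(axis=1)
        keep = np.argsort(totals)[-10:]
        expected = flat[keep].mean(axis=0)
        np.testing.assert_allclose(out.intensities, expected / expected.max(), atol=1e-12)
        np.testing.assert_allclose(out.intensities, b / b.max(), atol=1e-12)

    def test_scale_invariance(self, scheme):
        rng = np.random.default_rng(7)
        img = rng.uniform(0, 5, size=(2, 16, 16, scheme.m))
        base = extract_reference_spectrum(img, scheme).intensities
        scaled = extract_reference_spectrum(37.5 * img, scheme).intensities
        np.testing.assert_allclose(base, scaled, atol=1e-12)

    def test_mask_override_and_errors(self, scheme):
        img = np.ones((1, 4, 4, scheme.m))
        mask = np.zeros((1, 4, 4), dtype=bool)
        with pytest.raises(ValueError, match="empty selection"):
            extract_reference_spectrum(img, scheme, mask=mask)
        with pytest.raises(ValueError, match="all zero"):
            mask[0, 0, 0] = True
            extract_reference_spectrum(np.zeros_like(img), scheme, mask=mask)
        with pytest.raises(SchemeError):
            extract_reference_spectrum(np.ones((1, 4, 4, scheme.m + 2)), scheme)

    def test_recovers_simulator_response_noise_free(self, scheme, fluorophores):
        """Extraction from a noise-free 1-plex render equals the predicted
        response up to normalization."""
        f = fluorophores[4]
        scene = sim.SceneSpec(
            shape=(1, 16, 16),
            pixel_size=(1.0, 0.5, 0.5),
            channels=[sim.ChannelSpec(name=f.name, domains=[
                sim.Ellipsoid(center=(0.5, 4.0, 4.0), radii=(1.0, 2.0, 2.0), amplitude=3.0)
            ])],
            seed=0,
        )
        r = sim.render_spectral_image(scene, [f], np.zeros(scheme.m), scheme)
        out = extract_reference_spectrum(r.image, scheme)
        expected = sim.predict_response(f, scheme)
        np.testing.assert_allclose(out.intensities, expected / expected.max(), atol=1e-9)


class TestOptimizeAFChannel:
    def test_single_nonzero_entry(self):
        ex = (430.0, 470.0, 510.0)
        em = tuple(np.arange(440.0, 700.0, 10.0))
        inten = np.zeros((3, len(em)))
        inten[1, 10] = 5.0
        scan = EEMScan(ex, em, inten)
        af_ex, bands = optimize_af_channel(scan)
        assert af_ex == 470.0
        assert len(bands) == 4

    def test_separable_scan_peak_and_band_partition(self):
        model = sim.FluorophoreModel("af", 488.0, 30.0, 600.0, 40.0)
        ex = np.arange(430.0, 651.0, 2.0)
        em = np.arange(440.0, 801.0, 5.0)
        scan = sim.simulate_eem(model, ex, em)
        af_ex, bands = optimize_af_channel(scan, n_detectors=4)
        assert af_ex == 488.0
        # four contiguous equal-width bands covering [498, 800]
        widths = [b - a for a, b in bands]
        np.testing.assert_allclose(widths, widths[0])
        assert bands[0][0] == pytest.approx(498.0)
        assert bands[-1][1] == pytest.approx(800.0)
        for (a0, b0), (a1, _) in zip(bands, bands[1:]):
            assert b0 == pytest.approx(a1)

    def test_flat_scan_tie_breaks_to_shortest_wavelength(self):
        ex = (430.0, 470.0, 510.0)
        em = tuple(np.arange(560.0, 700.0, 10.0))  # red of every line + guard
        scan = EEMScan(ex, em, np.ones((3, len(em))))
        af_ex, _ = optimize_af_channel(scan)
        assert af_ex == 430.0

    def test_all_zero_scan_errors(self):
        scan = EEMScan((450.0,), (500.0, 550.0), np.zeros((1, 2)))
        with pytest.raises(ValueError, match="no autofluorescence"):
            optimize_af_channel(scan)

    def test_matches_exhaustive_row_sum_argmax(self):
        """Property: the selected line is the exhaustive argmax of guarded
        row sums on any input."""
        guard = 10.0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            ex = tuple(np.sort(rng.choice(np.arange(420.0, 650.0, 5.0), 8, replace=False)))
            em = tuple(np.arange(430.0, 801.0, 7.0))
            scan = EEMScan(ex, em, rng.uniform(0, 1, (8, len(em))))
            af_ex, _ = optimize_af_channel(scan, guard_nm=guard)
            sums = [
                sum(scan.intensity[i, j] for j, m in enumerate(em) if m >= e + guard)
                for i, e in enumerate(ex)
            ]
            assert af_ex == ex[int(np.argmax(sums))]


class TestConditionReport:
    def test_orthonormal_columns(self):
        rep = condition_report(np.eye(6)[:, :3])
        assert rep.condition_number == pytest.approx(1.0)
        assert rep.min_pairwise_angle_deg == pytest.approx(90.0)
        assert not rep.warn

    def test_duplicated_column_warns(self, scheme):
        v = np.linspace(0.5, 1.0, scheme.m)
        r = np.column_stack([v, v, np.linspace(1.0, 0.1, scheme.m)])
        rep = condition_report(r)
        assert rep.min_pairwise_angle_deg == pytest.approx(0.0, abs=1e-6)
        assert rep.warn
        assert rep.cosine_similarity[0, 1] == pytest.approx(1.0)
        assert rep.messages

    def test_condition_number_matches_svd_oracle(self):
        rng = np.random.default_rng(123)
        r = rng.uniform(0, 1, size=(26, 11))
        rep = condition_report(r)
        sv = np.linalg.svd(r, compute_uv=False)
        assert rep.condition_number == pytest.approx(sv[0] / sv[-1], rel=1e-12)


class TestReferenceMatrix:
    def test_duplicate_names_rejected(self, scheme):
        v = np.linspace(0.5, 1.0, scheme.m)
        s1 = ReferenceSpectrum("a", v, scheme)
        s2 = ReferenceSpectrum("a", v * 0.5, scheme)
        with pytest.raises(ValueError, match="duplicate"):
            ReferenceMatrix(scheme=scheme, spectra=[s1, s2], n_af=0)

    def test_eleven_column_fixture_matrix(self, reference_and_peaks):
        """Ten fluorophore references plus one AF reference stack into an
        11-column matrix with unit column peaks."""
        ref, _ = reference_and_peaks
        assert ref.c == 11
        assert ref.channel_names[-1] == "AF"
        np.testing.assert_allclose(ref.matrix.max(axis=0), 1.0)
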