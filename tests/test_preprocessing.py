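"""Spectral preprocessing: grid, SNR, filters, band areas, PCA denoising."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msh.preprocessing import (
    STANDARD_GRID,
    BandDefinition,
    PCADenoiser,
    Spectrum,
    band_area,
    compute_snr,
    default_bands,
    extract_features,
    moving_average_3x3,
    pca_denoise,
    remove_cosmic_rays,
    resample_spectrum,
    snr_filter,
)


class TestResample:
    def test_identity_on_standard_grid(self):
        s = Spectrum(STANDARD_GRID, np.sin(STANDARD_GRID / 100))
        out = resample_spectrum(s)
        np.testing.assert_array_equal(out.intensities, s.intensities)

    def test_linear_ramp_is_exact(self):
        wn = np.arange(395.0, 1806.0, 1.0)
        s = Spectrum(wn, 2.5 * wn - 7.0)
        out = resample_spectrum(s)
        np.testing.assert_allclose(out.intensities, 2.5 * STANDARD_GRID - 7.0, rtol=1e-12)

    def test_matches_two_point_interpolation_oracle(self):
        rng = np.random.default_rng(0)
        wn = np.sort(rng.uniform(390, 1810, 4000))
        wn[0], wn[-1] = 390.0, 1810.0
        y = rng.normal(size=wn.size)
        out = resample_spectrum(Spectrum(wn, y))
        # brute-force two-point formula
        for i in (0, 100, 350, 700):
            x = STANDARD_GRID[i]
            j = np.searchsorted(wn, x) - 1
            frac = (x - wn[j]) / (wn[j + 1] - wn[j])
            expected = y[j] * (1 - frac) + y[j + 1] * frac
            assert out.intensities[i] == pytest.approx(expected, abs=1e-10)

    def test_coverage_gap_rejected(self):
        with pytest.raises(ValueError, match="cm"):
            resample_spectrum(Spectrum(np.arange(500.0, 1801.0), np.zeros(1301)))


class TestCosmicRays:
    def test_single_spike_removed_others_untouched(self):
        rng = np.random.default_rng(1)
        base = 10 + rng.normal(0, 0.1, STANDARD_GRID.size)
        spiked = base.copy()
        spiked[300] += 10.0  # 100x the noise scale
        out = remove_cosmic_rays(Spectrum(STANDARD_GRID, spiked))
        assert out.intensities[300] < base[300] + 1.0
        untouched = np.delete(np.arange(701), [300])
        np.testing.assert_array_equal(out.intensities[untouched], spiked[untouched])

    def test_wide_band_preserved(self):
        rng = np.random.default_rng(2)
        y = 1 + 50 * np.exp(-0.5 * ((STANDARD_GRID - 1000) / 8) ** 2)
        y += rng.normal(0, 0.05, y.size)
        out = remove_cosmic_rays(Spectrum(STANDARD_GRID, y))
        np.testing.assert_array_equal(out.intensities, y)

    def test_flat_spectrum_unchanged(self):
        s = Spectrum(STANDARD_GRID, np.full(701, 3.0))
        np.testing.assert_array_equal(remove_cosmic_rays(s).intensities, s.intensities)


def _spectrum_with_snr(height: float, noise_pattern: np.ndarray) -> Spectrum:
    """Gaussian CH2 peak of known height + known noise in 1750-1800."""
    y = 0.01 * STANDARD_GRID  # linear background, absorbed by both baselines
    y += height * np.exp(-0.5 * ((STANDARD_GRID - 1450) / 5.0) ** 2)
    region = (STANDARD_GRID >= 1750) & (STANDARD_GRID <= 1800)
    y[region] += noise_pattern[: region.sum()]
    return Spectrum(STANDARD_GRID, y)


class TestSNR:
    def test_constructed_height_over_unit_noise(self):
        # alternating +/-1 has rms 1 and no linear trend
        noise = np.tile([1.0, -1.0], 13)
        s = _spectrum_with_snr(15.0, noise)
        assert compute_snr(s) == pytest.approx(15.0, rel=0.02)

    def test_scale_invariance(self):
        noise = np.tile([1.0, -1.0], 13)
        s = _spectrum_with_snr(8.0, noise)
        scaled = Spectrum(STANDARD_GRID, 10.0 * s.intensities)
        assert compute_snr(scaled) == pytest.approx(compute_snr(s), rel=1e-9)

    def test_noiseless_spectrum_flagged_infinite(self):
        s = _spectrum_with_snr(5.0, np.zeros(26))
        assert compute_snr(s) == np.inf

    def test_filter_counts_match_direct_counting(self):
        rng = np.random.default_rng(3)
        spectra = [
            _spectrum_with_snr(h, rng.normal(0, 1, 26))
            for h in rng.uniform(1, 30, 40)
        ]
        snrs = np.array([compute_snr(s) for s in spectra])
        for thr in (15.0, 7.0, 4.0):
            retained, discarded = snr_filter(spectra, thr)
            assert len(retained) == int((snrs >= thr).sum())
            assert len(retained) + len(discarded) == 40
        retained, _ = snr_filter(spectra, 1e-9)
        assert len(retained) == 40

    def test_strict_mode_excludes_boundary(self):
        noise = np.tile([1.0, -1.0], 13)
        s = _spectrum_with_snr(10.0, noise)
        snr = compute_snr(s)
        kept, _ = snr_filter([s], snr, strict=False)
        kept_strict, _ = snr_filter([s], snr, strict=True)
        assert len(kept) == 1 and len(kept_strict) == 0


class TestMovingAverage:
    def test_constant_raster_unchanged(self):
        raster = np.full((4, 5, 10), 2.0)
        np.testing.assert_allclose(moving_average_3x3(raster), raster)

    def test_interior_impulse_spreads_to_nine_cells(self):
        raster = np.zeros((5, 5, 3))
        raster[2, 2, :] = 9.0
        out = moving_average_3x3(raster)
        np.testing.assert_allclose(out[1:4, 1:4], 1.0)
        assert out[0, 0, 0] == 0.0

    def test_matches_nested_loop_oracle(self):
        rng = np.random.default_rng(4)
        raster = rng.normal(size=(5, 5, 7))
        out = moving_average_3x3(raster)
        for i in range(5):
            for j in range(5):
                acc, cnt = np.zeros(7), 0
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        if 0 <= i + di < 5 and 0 <= j + dj < 5:
                            acc += raster[i + di, j + dj]
                            cnt += 1
                np.testing.assert_allclose(out[i, j], acc / cnt, atol=1e-12)

    def test_rejects_non_raster(self):
        with pytest.raises(ValueError):
            moving_average_3x3(np.zeros((4, 10)))


class TestBandArea:
    def test_linear_spectrum_gives_zero_for_every_band(self):
        s = Spectrum(STANDARD_GRID, 3.0 * STANDARD_GRID + 11.0)
        for band in default_bands():
            assert band_area(s, band) == pytest.approx(0.0, abs=1e-9)

    def test_gaussian_area_matches_analytic(self):
        sigma, height = 3.0, 2.0
        y = 0.002 * STANDARD_GRID + height * np.exp(
            -0.5 * ((STANDARD_GRID - 1092) / sigma) ** 2
        )
        area = band_area(Spectrum(STANDARD_GRID, y), BandDefinition(1092, 12.0))
        analytic = height * sigma * np.sqrt(2 * np.pi)
        assert area == pytest.approx(analytic, rel=0.02)

    @given(offset=st.floats(-100, 100))
    @settings(max_examples=20, deadline=None)
    def test_offset_invariance(self, offset):
        rng = np.random.default_rng(5)
        y = rng.normal(size=701)
        band = BandDefinition(906)
        a0 = band_area(Spectrum(STANDARD_GRID, y), band)
        a1 = band_area(Spectrum(STANDARD_GRID, y + offset), band)
        assert a1 == pytest.approx(a0, abs=1e-8)

    def test_window_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            BandDefinition(1798, 8.0)


class TestFeatures:
    def test_unit_norm(self):
        rng = np.random.default_rng(6)
        f = extract_features(Spectrum(STANDARD_GRID, rng.normal(size=701)))
        assert np.linalg.norm(f) == pytest.approx(1.0, abs=1e-9)
        assert f.shape == (13,)

    @given(scale=st.floats(1e-3, 1e3))
    @settings(max_examples=20, deadline=None)
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(7)
        y = rng.normal(size=701) + 5
        f0 = extract_features(Spectrum(STANDARD_GRID, y))
        f1 = extract_features(Spectrum(STANDARD_GRID, scale * y))
        np.testing.assert_allclose(f1, f0, atol=1e-9)

    def test_featureless_spectrum_rejected(self):
        with pytest.raises(ValueError, match="featureless"):
            extract_features(Spectrum(STANDARD_GRID, np.full(701, 2.0)))


class TestPCADenoise:
    def _basis(self, n=120, seed=8):
        rng = np.random.default_rng(seed)
        return [Spectrum(STANDARD_GRID, rng.normal(size=701)) for _ in range(n)]

    def test_idempotent(self):
        basis = self._basis()
        rng = np.random.default_rng(9)
        spectra = [Spectrum(STANDARD_GRID, rng.normal(size=701)) for _ in range(5)]
        once = pca_denoise(spectra, basis, 50)
        twice = pca_denoise(once, basis, 50)
        for a, b in zip(once, twice):
            np.testing.assert_allclose(a.intensities, b.intensities, atol=1e-8)

    def test_residual_orthogonal_to_components(self):
        basis = self._basis()
        den = PCADenoiser(50).fit(basis)
        rng = np.random.default_rng(10)
        s = Spectrum(STANDARD_GRID, rng.normal(size=701))
        out = den.transform([s])[0]
        resid = s.intensities - out.intensities
        assert np.max(np.abs(den.components_ @ resid)) < 1e-8

    def test_in_span_spectrum_reconstructed(self):
        basis = self._basis()
        den = PCADenoiser(50).fit(basis)
        out = den.transform([basis[0]])[0]
        again = den.transform([out])[0]
        np.testing.assert_allclose(out.intensities, again.intensities, atol=1e-8)

    def test_white_noise_variance_reduced_to_rank_fraction(self):
        # projecting fresh white noise onto a 50-dim subspace keeps
        # ~50/701 of its variance
        basis = self._basis(200, seed=11)
        den = PCADenoiser(50).fit(basis)
        rng = np.random.default_rng(12)
        fresh = [Spectrum(STANDARD_GRID, rng.normal(size=701)) for _ in range(300)]
        out = den.transform(fresh)
        var_in = np.var([s.intensities for s in fresh])
        mean_out = np.mean([s.intensities for s in out], axis=0)
        var_out = np.var([s.intensities - mean_out for s in out])
        assert var_out / var_in == pytest.approx(50 / 701, rel=0.25)

    def test_small_basis_rejected(self):
        with pytest.raises(ValueError):
            PCADenoiser(50).fit(self._basis(30))
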