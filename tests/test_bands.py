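"""GMG band shape: closed form vs brute-force convolution, limits, areas."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import afdecon as af
from afdecon.bands import GMGBand, basis_matrix, nm_to_wavenumber


def convolution_oracle(nu, center_cm1, sigma_g, sigma_h, skew):
    """Discrete convolution of a Gaussian with a one-sided half-Gaussian.

    Independent numerical route to the same unit-area profile the closed
    form claims to compute.
    """
    dnu = 0.5
    m = int(10 * np.hypot(sigma_g, sigma_h) / dnu)
    x = np.arange(-m, m + 1) * dnu  # symmetric odd grid keeps 'same' centered
    gauss = np.exp(-0.5 * (x / sigma_g) ** 2) / (sigma_g * np.sqrt(2 * np.pi))
    half = np.where(x >= 0, np.exp(-0.5 * (x / sigma_h) ** 2), 0.0)
    half *= np.sqrt(2 / np.pi) / sigma_h
    sign = -1.0 if skew == "red" else 1.0
    conv = np.convolve(gauss, half, mode="same") * dnu
    # red skew shifts toward lower wavenumber: mirror the half-Gaussian axis
    grid = center_cm1 + sign * x
    order = np.argsort(grid)
    return np.interp(nu, grid[order], conv[order])


class TestGMGProfile:
    @pytest.mark.parametrize("skew", ["red", "blue"])
    def test_matches_numeric_convolution(self, skew):
        band = GMGBand(
            center_nm=500.0, sigma_g_cm1=300.0, sigma_h_cm1=600.0, skew=skew
        )
        nu = np.linspace(band.center_wavenumber - 6000, band.center_wavenumber + 6000, 4001)
        closed = af.gmg_profile(nu, band)
        oracle = convolution_oracle(nu, band.center_wavenumber, 300.0, 600.0, skew)
        assert np.max(np.abs(closed - oracle)) <= 1e-6

    def test_sigma_h_zero_is_gaussian(self):
        band = GMGBand(center_nm=500.0, sigma_g_cm1=400.0, sigma_h_cm1=0.0)
        nu = np.linspace(band.center_wavenumber - 4000, band.center_wavenumber + 4000, 2001)
        gauss = np.exp(-0.5 * ((nu - band.center_wavenumber) / 400.0) ** 2)
        gauss /= 400.0 * np.sqrt(2 * np.pi)
        np.testing.assert_allclose(af.gmg_profile(nu, band), gauss, atol=1e-12)

    def test_sigma_h_limit_converges_to_gaussian(self):
        # sup-norm convergence as sigma_h -> 0
        band0 = GMGBand(center_nm=500.0, sigma_g_cm1=400.0, sigma_h_cm1=0.0)
        band = GMGBand(center_nm=500.0, sigma_g_cm1=400.0, sigma_h_cm1=400.0 * 1e-6)
        nu = np.linspace(16000, 24000, 2001)
        diff = np.abs(af.gmg_profile(nu, band) - af.gmg_profile(nu, band0))
        assert diff.max() < 1e-8

    @given(
        center=st.floats(420, 700),
        sg=st.floats(200, 2000),
        ratio=st.floats(0, 3),
        skew=st.sampled_from(["red", "blue"]),
    )
    @settings(max_examples=50, deadline=None)
    def test_nonnegative_and_unit_area(self, center, sg, ratio, skew):
        band = GMGBand(
            center_nm=center, sigma_g_cm1=sg, sigma_h_cm1=sg * ratio, skew=skew
        )
        om = band.omega
        nu = np.linspace(band.center_wavenumber - 8 * om, band.center_wavenumber + 8 * om, 8001)
        y = af.gmg_profile(nu, band)
        assert np.all(y >= 0)
        assert np.trapezoid(y, nu) == pytest.approx(1.0, rel=1e-6)

    def test_area_parameter_scales_profile(self):
        band = GMGBand(center_nm=500.0, sigma_g_cm1=400.0, sigma_h_cm1=500.0, area=7.5)
        nu = np.linspace(15000, 25000, 501)
        unit = band.model_copy(update={"area": 1.0})
        np.testing.assert_allclose(
            af.gmg_profile(nu, band), 7.5 * af.gmg_profile(nu, unit), rtol=1e-12
        )

    def test_sigma_g_zero_rejected(self):
        with pytest.raises(Exception):
            GMGBand(center_nm=500.0, sigma_g_cm1=0.0, sigma_h_cm1=100.0)


class TestCompose:
    def test_single_band_equals_profile(self, serum_lib):
        f = serum_lib.fluorophores[0]
        single = af.BandLibrary(tissue="serum", fluorophores=(f,))
        nu = nm_to_wavenumber(np.arange(400.0, 751.0))
        np.testing.assert_allclose(
            af.compose(single, nu), af.gmg_profile(nu, f.bands[0]), rtol=1e-12
        )

    @given(scale=st.floats(0.1, 10))
    @settings(max_examples=20, deadline=None)
    def test_homogeneous_in_areas(self, liver_lib, scale):
        nu = nm_to_wavenumber(np.arange(400.0, 751.0, 5.0))
        areas = np.linspace(1, 8, liver_lib.n_bands)
        np.testing.assert_allclose(
            af.compose(liver_lib, nu, areas * scale),
            scale * af.compose(liver_lib, nu, areas),
            rtol=1e-9,
        )

    def test_additive(self, liver_lib):
        nu = nm_to_wavenumber(np.arange(400.0, 751.0, 5.0))
        a = np.linspace(1, 8, liver_lib.n_bands)
        b = np.linspace(8, 1, liver_lib.n_bands)
        np.testing.assert_allclose(
            af.compose(liver_lib, nu, a + b),
            af.compose(liver_lib, nu, a) + af.compose(liver_lib, nu, b),
            rtol=1e-9,
        )

    def test_band_areas_recovered_by_integration(self, liver_lib):
        # compose with known areas on a wide fine grid, re-integrate per band
        nu = np.linspace(2000, 35000, 66001)
        B = basis_matrix(liver_lib, nu)
        areas = np.arange(1.0, liver_lib.n_bands + 1)
        for j in range(liver_lib.n_bands):
            integ = np.trapezoid(areas[j] * B[:, j], nu)
            assert integ == pytest.approx(areas[j], rel=1e-4)


class TestBandPeakWavelength:
    def test_symmetric_band_peaks_at_center(self):
        band = GMGBand(center_nm=520.0, sigma_g_cm1=500.0, sigma_h_cm1=0.0)
        assert af.band_peak_wavelength(band) == pytest.approx(520.0)

    @pytest.mark.parametrize(
        "skew,expect_longer", [("red", True), ("blue", False)]
    )
    def test_skew_displaces_peak(self, skew, expect_longer):
        band = GMGBand(center_nm=520.0, sigma_g_cm1=500.0, sigma_h_cm1=900.0, skew=skew)
        peak = af.band_peak_wavelength(band)
        assert (peak > 520.0) == expect_longer
        # dense-grid argmax oracle
        nu = np.linspace(band.center_wavenumber - 5000, band.center_wavenumber + 5000, 200001)
        y = af.gmg_profile(nu, band)
        oracle = 1e7 / nu[np.argmax(y)]
        assert peak == pytest.approx(oracle, abs=0.05)

    def test_invariant_under_area_scaling(self):
        b1 = GMGBand(center_nm=520.0, sigma_g_cm1=500.0, sigma_h_cm1=900.0, area=1.0)
        b2 = b1.model_copy(update={"area": 123.0})
        assert af.band_peak_wavelength(b1) == pytest.approx(
            af.band_peak_wavelength(b2), abs=1e-6
        )
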