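import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from canopyflux import (
    BLUE,
    AbsorptanceSpectrum,
    PhotoconversionCoefficients,
    SpectralDistribution,
    Waveband,
    compute_ppe,
    daily_light_integral,
    default_photoconversion_coefficients,
    integrate_photon_flux,
    leaf_photon_absorption,
    make_led_spectrum,
    waveband_fractions,
)
from canopyflux.synthetic import DEFAULT_TREATMENTS

WL = np.arange(380.0, 781.0, 1.0)


def spectrum_from(flux):
    return SpectralDistribution(WL, flux)


positive_spectra = arrays(
    float, WL.shape, elements=st.floats(0.0, 10.0)
).filter(lambda f: f.sum() > 1.0).map(spectrum_from)


class TestIntegratePhotonFlux:
    def test_flat_spectrum_band_integral_is_band_width(self, flat_spectrum):
        assert integrate_photon_flux(flat_spectrum, BLUE) == pytest.approx(100.0)

    def test_zero_spectrum_integrates_to_zero(self):
        s = spectrum_from(np.zeros_like(WL))
        assert integrate_photon_flux(s, Waveband(410, 740)) == 0.0

    def test_gaussian_peak_matches_fine_grid_quadrature(self):
        # Oracle: the same Gaussian integrated by trapezoid on a 0.01 nm grid.
        def gauss(wl):
            return 50.0 / (8.0 * np.sqrt(2 * np.pi)) * np.exp(
                -((wl - 550.0) ** 2) / (2 * 8.0**2)
            )

        fine = np.arange(500.0, 600.01, 0.01)
        oracle = np.trapezoid(gauss(fine), fine)
        s = spectrum_from(gauss(WL))
        got = integrate_photon_flux(s, Waveband(500, 600))
        assert got == pytest.approx(oracle, rel=1e-4)
        assert got == pytest.approx(50.0, rel=1e-3)

    def test_band_outside_grid_raises(self, flat_spectrum):
        with pytest.raises(ValueError, match="outside"):
            integrate_photon_flux(flat_spectrum, Waveband(300, 500))

    @given(positive_spectra)
    @settings(max_examples=25, deadline=None)
    def test_additive_over_adjacent_bands(self, spectrum):
        parts = sum(
            integrate_photon_flux(spectrum, b)
            for b in (Waveband(400, 500), Waveband(500, 600), Waveband(600, 700))
        )
        whole = integrate_photon_flux(spectrum, Waveband(400, 700))
        assert parts == pytest.approx(whole, abs=1e-9 * max(whole, 1.0))


class TestWavebandFractions:
    def test_flat_spectrum_fractions_are_band_width_ratios(self, flat_spectrum):
        f = waveband_fractions(flat_spectrum)
        assert f["blue"] == pytest.approx(100 / 350)
        assert f["far_red"] == pytest.approx(50 / 350)

    def test_narrow_blue_peak_gives_pure_blue(self):
        flux = np.exp(-((WL - 450.0) ** 2) / (2 * 4.0**2))
        f = waveband_fractions(spectrum_from(flux))
        assert f["blue"] == pytest.approx(1.0, abs=1e-9)
        assert f["red"] == pytest.approx(0.0, abs=1e-9)

    def test_default_rb_spectrum_blue_fraction(self):
        f = waveband_fractions(make_led_spectrum(DEFAULT_TREATMENTS[0]))
        assert f["blue"] * 100 == pytest.approx(31.5, abs=0.3)

    def test_zero_flux_raises(self):
        with pytest.raises(ValueError, match="zero total flux"):
            waveband_fractions(spectrum_from(np.zeros_like(WL)))

    @given(positive_spectra)
    @settings(max_examples=25, deadline=None)
    def test_fractions_sum_to_one(self, spectrum):
        assert sum(waveband_fractions(spectrum).values()) == pytest.approx(
            1.0, abs=1e-9
        )


class TestDailyLightIntegral:
    @pytest.mark.parametrize(
        "ppfd,hours,expected",
        [(350, 14, 17.64), (0, 14, 0.0), (100, 10, 3.6)],
    )
    def test_values(self, ppfd, hours, expected):
        assert daily_light_integral(ppfd, hours) == pytest.approx(expected)

    def test_negative_input_raises(self):
        with pytest.raises(ValueError):
            daily_light_integral(-1, 14)


class TestComputePpe:
    def test_spectrum_on_pure_pr_support_gives_one(self):
        coeffs = PhotoconversionCoefficients(WL, np.ones_like(WL), np.zeros_like(WL))
        s = spectrum_from(np.exp(-((WL - 660.0) ** 2) / 50.0))
        assert compute_ppe(s, coeffs) == pytest.approx(1.0)

    def test_equal_cross_sections_give_half(self, flat_spectrum):
        coeffs = PhotoconversionCoefficients(
            WL, 0.7 * np.ones_like(WL), 0.7 * np.ones_like(WL)
        )
        assert compute_ppe(flat_spectrum, coeffs) == pytest.approx(0.5)

    def test_rb_spectrum_with_bundled_table(self):
        # High-PPE red/blue spectrum; the bundled table is a synthetic
        # approximation, hence the wide tolerance.
        s = make_led_spectrum(DEFAULT_TREATMENTS[0])
        assert compute_ppe(s, default_photoconversion_coefficients()) == pytest.approx(
            0.87, abs=0.05
        )

    def test_far_red_lowers_ppe(self):
        coeffs = default_photoconversion_coefficients()
        rb = compute_ppe(make_led_spectrum(DEFAULT_TREATMENTS[0]), coeffs)
        rb_fr = compute_ppe(make_led_spectrum(DEFAULT_TREATMENTS[1]), coeffs)
        assert rb_fr < rb

    @given(st.floats(0.01, 100.0))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, factor):
        coeffs = default_photoconversion_coefficients()
        s = make_led_spectrum(DEFAULT_TREATMENTS[2])
        assert compute_ppe(s.scaled(factor), coeffs) == pytest.approx(
            compute_ppe(s, coeffs), abs=1e-12
        )


class TestLeafPhotonAbsorption:
    def test_perfect_absorber(self, flat_spectrum):
        leaf = AbsorptanceSpectrum(WL, np.ones_like(WL))
        assert leaf_photon_absorption(flat_spectrum, leaf) == pytest.approx(1.0)

    def test_uniform_half_absorber_for_any_spectrum(self):
        leaf = AbsorptanceSpectrum(WL, 0.5 * np.ones_like(WL))
        s = make_led_spectrum(DEFAULT_TREATMENTS[3])
        assert leaf_photon_absorption(s, leaf) == pytest.approx(0.5)

    def test_piecewise_absorptance_hand_arithmetic(self):
        # flat spectrum on exactly 400-750; a = 0.9 below 700, 0.2 above
        wl = np.arange(400.0, 750.5, 0.5)
        s = SpectralDistribution(wl, np.ones_like(wl))
        a = np.where(wl < 700.0, 0.9, 0.2)
        a[wl == 700.0] = 0.9
        got = leaf_photon_absorption(s, AbsorptanceSpectrum(wl, a))
        assert got == pytest.approx((0.9 * 300 + 0.2 * 50) / 350, abs=2e-3)

    @given(st.floats(0.0, 0.3))
    @settings(max_examples=25, deadline=None)
    def test_monotone_in_absorptance(self, bump):
        s = make_led_spectrum(DEFAULT_TREATMENTS[0])
        base = 0.5 * np.ones_like(WL)
        lo = leaf_photon_absorption(s, AbsorptanceSpectrum(WL, base))
        hi = leaf_photon_absorption(
            s, AbsorptanceSpectrum(WL, np.clip(base + bump, 0, 1))
        )
        assert hi >= lo - 1e-12


class TestValidation:
    def test_grid_must_increase(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            SpectralDistribution(WL[::-1], np.ones_like(WL))

    def test_grid_must_span_400_750(self):
        wl = np.arange(450.0, 701.0)
        with pytest.raises(ValueError, match="span"):
            SpectralDistribution(wl, np.ones_like(wl))

    def test_negative_flux_rejected(self):
        flux = np.ones_like(WL)
        flux[10] = -1
        with pytest.raises(ValueError, match="nonnegative"):
            SpectralDistribution(WL, flux)

    def test_absorptance_bounded(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            AbsorptanceSpectrum(WL, 1.2 * np.ones_like(WL))
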