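"""Spectral types, presets, chromaticity and sRGB rendering."""

import numpy as np
import pytest

from bilistrip import errors, spectra
from bilistrip.spectra import (
    CameraResponse,
    ReflectanceSpectrum,
    SpectralPowerDistribution,
    cie_xy,
    default_camera,
    load_cmf,
    peak_wavelength,
    spd_preset,
    spd_to_srgb,
    spectral_product,
    srgb_decode,
    srgb_encode,
)


class TestPresets:
    @pytest.mark.parametrize("name,peak,support", [
        ("d2", 238.8, (190.0, 780.0)),
        ("h2", 583.8, (380.0, 930.0)),
        ("mini_led", 580.4, (380.0, 780.0)),
    ])
    def test_peak_and_support(self, name, peak, support):
        spd = spd_preset(name)
        assert peak_wavelength(spd) == pytest.approx(peak)
        assert spd.support == support

    def test_unknown_preset_raises(self):
        with pytest.raises(errors.PresetNotFoundError):
            spd_preset("xenon")

    def test_mini_led_zero_outside_support(self):
        spd = spd_preset("mini_led")
        assert spd.resample(np.array([300.0, 350.0, 800.0])).tolist() == [0, 0, 0]

    def test_mini_led_has_blue_pump_lobe(self):
        spd = spd_preset("mini_led")
        lam, inten = spd.wavelengths_nm, spd.intensities
        in_pump = inten[(lam > 445) & (lam < 455)].max()
        valley = inten[(lam > 465) & (lam < 480)].min()
        assert in_pump > 1.5 * valley  # distinct local lobe near 450 nm


class TestPeakWavelength:
    def test_single_support_point(self):
        spd = SpectralPowerDistribution([400.0, 500.0, 600.0], [0.0, 2.0, 0.0])
        assert peak_wavelength(spd) == 500.0

    def test_tie_breaks_to_smallest_wavelength(self):
        lam = np.arange(380.0, 781.0)
        spd = SpectralPowerDistribution(lam, np.ones_like(lam))
        assert peak_wavelength(spd) == 380.0

    def test_all_zero_raises(self):
        spd = SpectralPowerDistribution([400.0, 500.0], [0.0, 0.0])
        with pytest.raises(errors.DegenerateSpectrumError):
            peak_wavelength(spd)


class TestSpectralProduct:
    def test_identity_reflector_returns_input_values(self):
        spd = spd_preset("mini_led")
        ones = ReflectanceSpectrum([380.0, 780.0], [1.0, 1.0])
        out = spectral_product(spd, ones)
        np.testing.assert_allclose(out.resample(spd.wavelengths_nm),
                                   spd.intensities, atol=1e-12)
        assert peak_wavelength(out) == peak_wavelength(spd)

    def test_perfect_absorber_gives_zero(self):
        spd = spd_preset("h2")
        black = ReflectanceSpectrum([380.0, 930.0], [0.0, 0.0])
        assert np.all(spectral_product(spd, black).intensities == 0)

    def test_single_bin_pointwise_product(self):
        p = SpectralPowerDistribution([550.0], [2.0])
        r = ReflectanceSpectrum([500.0, 600.0], [0.5, 0.5])
        out = spectral_product(p, r)
        assert out.wavelengths_nm.tolist() == [550.0]
        assert out.intensities.tolist() == [1.0]

    def test_commutative_and_never_amplifies(self, rng):
        lam = np.arange(400.0, 701.0, 5.0)
        p = SpectralPowerDistribution(lam, rng.uniform(0, 2, lam.size))
        r = ReflectanceSpectrum(lam, rng.uniform(0, 1, lam.size))
        out = spectral_product(p, r)
        assert np.all(out.intensities <= p.resample(out.wavelengths_nm) + 1e-12)
        # commutativity in value: swap roles through a reflectance wrapper
        swapped = spectral_product(
            SpectralPowerDistribution(lam, r.reflectance),
            ReflectanceSpectrum(lam, np.clip(p.intensities / 2.0, 0, 1)))
        direct = spectral_product(
            p, ReflectanceSpectrum(lam, r.reflectance))
        np.testing.assert_allclose(direct.intensities / 2.0,
                                   swapped.intensities, atol=1e-12)

    def test_disjoint_ranges_raise(self):
        p = SpectralPowerDistribution([400.0, 450.0], [1.0, 1.0])
        r = ReflectanceSpectrum([600.0, 650.0], [1.0, 1.0])
        with pytest.raises(errors.NoOverlapError):
            spectral_product(p, r)


class TestChromaticity:
    def test_equal_energy_white_point(self):
        lam = np.arange(380.0, 781.0)
        spd = SpectralPowerDistribution(lam, np.ones_like(lam))
        xy = cie_xy(spd)
        assert xy.x == pytest.approx(1 / 3, abs=2e-3)
        assert xy.y == pytest.approx(1 / 3, abs=2e-3)

    def test_monochromatic_matches_cmf_row_ratio(self):
        lam, cmf = load_cmf()
        row = cmf[np.where(lam == 550.0)[0][0]]
        xy = cie_xy(SpectralPowerDistribution([550.0], [1.0]))
        assert xy.x == pytest.approx(row[0] / row.sum(), abs=1e-9)
        assert xy.y == pytest.approx(row[1] / row.sum(), abs=1e-9)

    def test_all_zero_raises(self):
        spd = SpectralPowerDistribution([400.0, 500.0], [0.0, 0.0])
        with pytest.raises(errors.DegenerateSpectrumError):
            cie_xy(spd)

    @pytest.mark.parametrize("name", ["d2", "h2", "mini_led"])
    def test_presets_inside_gamut(self, name):
        xy = cie_xy(spd_preset(name))
        assert xy.x >= 0 and xy.y > 0 and xy.x + xy.y <= 1


class TestSrgbRendering:
    def test_all_zero_spd_renders_black(self):
        spd = SpectralPowerDistribution([400.0, 700.0], [0.0, 0.0])
        assert spd_to_srgb(spd, default_camera()).tolist() == [0, 0, 0]

    def test_doubling_power_equals_doubling_exposure(self, rng):
        lam = np.arange(400.0, 701.0, 1.0)
        inten = rng.uniform(0, 1, lam.size) * 1e-3
        spd = SpectralPowerDistribution(lam, inten)
        doubled = SpectralPowerDistribution(lam, 2 * inten)
        cam = default_camera(exposure_scale=1.0)
        assert (spd_to_srgb(doubled, cam).tolist()
                == spd_to_srgb(spd, default_camera(2.0)).tolist())

    def test_nonpositive_exposure_raises(self):
        spd = spd_preset("mini_led")
        with pytest.raises(errors.ConfigurationError):
            spd_to_srgb(spd, default_camera(exposure_scale=0.0))

    def test_blank_paper_green_matches_mini_led_intercept(self):
        # Physical chain: lamp x blank reflectance -> camera with the
        # calibrated exposure reproduces the published blank grayscale.
        from bilistrip.synthetic import BLANK_REFLECTANCE, calibrated_exposure
        spd = spd_preset("mini_led")
        blank = ReflectanceSpectrum([380.0, 780.0],
                                    [BLANK_REFLECTANCE, BLANK_REFLECTANCE])
        cam = default_camera(exposure_scale=calibrated_exposure("mini_led"))
        rgb = spd_to_srgb(spectral_product(spd, blank), cam)
        assert abs(float(rgb[1]) - 221.81) <= 2.0

    def test_srgb_round_trip_exact_on_all_byte_values(self):
        v = np.arange(256) / 255.0
        back = np.floor(255.0 * srgb_encode(srgb_decode(v)) + 0.5).astype(int)
        assert back.tolist() == list(range(256))


class TestValidation:
    def test_decreasing_grid_rejected(self):
        with pytest.raises(ValueError):
            SpectralPowerDistribution([500.0, 400.0], [1.0, 1.0])

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            SpectralPowerDistribution([400.0, 500.0], [1.0, -0.1])

    def test_reflectance_above_one_rejected(self):
        with pytest.raises(ValueError):
            ReflectanceSpectrum([400.0, 500.0], [0.5, 1.2])

    def test_camera_needs_visible_band_power(self):
        lam = np.arange(380.0, 781.0)
        with pytest.raises(ValueError):
            CameraResponse(lam, np.zeros(lam.size), np.ones(lam.size),
                           np.ones(lam.size))
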