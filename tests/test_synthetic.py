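"""Synthetic calibration tables, reflectance model and strip rendering."""

import io

import imageio.v3 as iio
import numpy as np
import pytest

from bilistrip import errors, roi, synthetic
from bilistrip.calibration import fit_line
from bilistrip.synthetic import (
    ResponsePreset,
    biliverdin_reflectance,
    default_concentration_series,
    fixture_strip_sigmas,
    generate_calibration_table,
    mean_gray,
    noiseless_channel_series,
    render_strip_image,
    response_preset,
    sigma_for_median_r2,
)


class TestConcentrationSeries:
    def test_range_count_and_spacing(self):
        c = default_concentration_series()
        assert len(c) == 12
        assert c[0] == pytest.approx(0.1)
        assert c[-1] == pytest.approx(2.0)
        assert np.all(np.diff(c) > 0)
        np.testing.assert_allclose(np.diff(c), 19 / 110)


class TestResponsePresets:
    @pytest.mark.parametrize("light,slope,intercept", [
        ("mini_led", -6.2971, 221.81),
        ("h2", -6.2029, 221.72),
        ("d2", -1.8078, 231.56),
    ])
    def test_green_lines(self, light, slope, intercept):
        p = response_preset(light, "G")
        assert (p.slope, p.intercept) == (slope, intercept)
        assert p.slope < 0

    def test_lod_variant_sigmas(self):
        assert response_preset("mini_led", "G", "lod").residual_sd == 1.17551
        assert response_preset("h2", "G", "lod").residual_sd == 1.42667
        with pytest.raises(errors.PresetNotFoundError):
            response_preset("d2", "G", "lod")   # no published D2 LOD

    def test_unknown_names_raise(self):
        with pytest.raises(errors.PresetNotFoundError):
            response_preset("xenon", "G")
        with pytest.raises(errors.PresetNotFoundError):
            response_preset("mini_led", "Q")

    @pytest.mark.parametrize("light", synthetic.LIGHT_SOURCES)
    def test_derived_rb_presets_have_negative_slopes(self, light):
        for ch in ("R", "B"):
            p = response_preset(light, ch)
            assert p.slope < 0
            assert p.residual_sd > 0


class TestMeanGray:
    def test_published_line_values(self):
        g = response_preset("mini_led", "G")
        assert mean_gray(0.0, g) == pytest.approx(221.81)
        assert mean_gray(1.0, g) == pytest.approx(215.5129)

    def test_clipping_at_zero(self):
        p = ResponsePreset("mini_led", "G", slope=-300.0, intercept=100.0,
                           residual_sd=0.0)
        assert mean_gray(2.0, p) == 0.0

    def test_negative_concentration_raises(self):
        with pytest.raises(errors.DomainError):
            mean_gray(-0.1, response_preset("mini_led", "G"))

    def test_affine_and_nonincreasing_before_clipping(self):
        p = response_preset("h2", "G")
        c = np.linspace(0, 2, 50)
        y = np.array([mean_gray(x, p) for x in c])
        assert np.all(np.diff(y) <= 0)


class TestCalibrationTables:
    def test_noiseless_table_is_the_line(self):
        ds = generate_calibration_table([0.5, 1.0, 1.5],
                                        response_preset("mini_led", "G"),
                                        sigma=0.0, seed=1)
        assert ds.channel_means("G")[1] == pytest.approx(215.5129)

    def test_same_seed_reproduces_table(self):
        p = response_preset("h2", "G")
        a = generate_calibration_table(default_concentration_series(), p, seed=42)
        b = generate_calibration_table(default_concentration_series(), p, seed=42)
        np.testing.assert_array_equal(a.channel_means("G"), b.channel_means("G"))

    def test_noiseless_fit_recovers_line_exactly(self):
        p = response_preset("mini_led", "G")
        ds = generate_calibration_table(default_concentration_series(), p,
                                        sigma=0.0, seed=0)
        fit = fit_line(ds, "G")
        assert fit.slope == pytest.approx(p.slope, rel=1e-9)
        assert fit.intercept == pytest.approx(p.intercept, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_negative_sigma_raises(self):
        with pytest.raises(errors.ConfigurationError):
            generate_calibration_table([1.0], response_preset("d2", "G"),
                                       sigma=-1.0)


class TestReflectanceModel:
    def test_blank_paper_at_zero_concentration(self):
        r = biliverdin_reflectance(0.0)
        np.testing.assert_allclose(r.reflectance, synthetic.BLANK_REFLECTANCE)

    def test_beer_lambert_monotonicity_in_concentration(self):
        r1 = biliverdin_reflectance(0.4)
        r2 = biliverdin_reflectance(1.3)
        assert np.all(r2.reflectance <= r1.reflectance)

    def test_negative_concentration_raises(self):
        with pytest.raises(errors.DomainError):
            biliverdin_reflectance(-0.5)

    def test_rendered_green_strictly_decreases_over_series(self):
        g = noiseless_channel_series("mini_led")["G"]
        assert np.all(np.diff(g) < 0)

    @pytest.mark.parametrize("light,printed_slope", [
        ("mini_led", -6.2971), ("d2", -1.8078),
    ])
    def test_rendered_green_slope_matches_printed_line(self, light, printed_slope):
        c = default_concentration_series()
        g = noiseless_channel_series(light)["G"]
        slope = np.polyfit(c, g, 1)[0]
        assert slope == pytest.approx(printed_slope, rel=0.05)


class TestRenderStripImage:
    def test_background_exact_when_noiseless(self):
        img = render_strip_image(0.5, noise_sd=0.0, size_px=150, seed=0)
        assert tuple(img.pixels[0, 0]) == (40, 40, 40)
        assert tuple(img.pixels[-1, -1]) == (40, 40, 40)

    def test_noiseless_green_mean_tracks_published_line(self):
        # image-level and measurement-level generators must agree
        g_preset = response_preset("mini_led", "G")
        mask = roi.circular_roi_mask(130, 130)
        for c in (0.1, 0.5, 1.0):
            img = render_strip_image(c, light="mini_led", noise_sd=0.0,
                                     size_px=150, seed=0)
            stats = roi.channel_stats(img, mask.with_origin(10, 10))
            assert abs(stats.mean[1] - mean_gray(c, g_preset)) <= 2.0

    def test_same_seed_bit_identical_png(self, tmp_path):
        imgs = [render_strip_image(1.2, light="d2", noise_sd=2.0, seed=99)
                for _ in range(2)]
        payloads = []
        for img in imgs:
            buf = io.BytesIO()
            iio.imwrite(buf, img.pixels, extension=".png")
            payloads.append(buf.getvalue())
        assert payloads[0] == payloads[1]

    def test_disc_larger_than_image_raises(self):
        with pytest.raises(errors.GeometryError):
            render_strip_image(1.0, size_px=100, disc_diameter_px=130)

    def test_clipped_fraction_below_one_percent(self):
        img = render_strip_image(0.1, light="mini_led", noise_sd=2.0, seed=3)
        px = img.pixels
        frac = np.mean((px == 0) | (px == 255))
        assert frac < 0.01

    def test_metadata_records_acquisition(self):
        img = render_strip_image(0.7, light="h2", seed=11)
        assert img.metadata["light_source"] == "h2"
        assert img.metadata["concentration_mg_dl"] == 0.7
        assert img.metadata["pixel_pitch_mm"] == pytest.approx(30 / 130)


class TestFixtureNoiseModel:
    def test_green_sigma_preserves_published_noise_to_signal(self):
        # sigma_G scaled by rendered/published slope ratio: the fitted R^2
        # distribution then matches the published one for every lamp.
        c = default_concentration_series()
        sxx = ((c - c.mean()) ** 2).sum()
        for light in synthetic.LIGHT_SOURCES:
            g = noiseless_channel_series(light)["G"]
            rendered = np.polyfit(c, g, 1)[0]
            sig = fixture_strip_sigmas(light)
            printed = response_preset(light, "G")
            lam_rendered = rendered ** 2 * sxx / sig["G"] ** 2
            lam_printed = printed.slope ** 2 * sxx / printed.residual_sd ** 2
            assert lam_rendered == pytest.approx(lam_printed, rel=1e-6)

    def test_sigma_for_median_r2_round_trip(self):
        c = default_concentration_series()
        sigma = sigma_for_median_r2(-6.2971, 0.9313, c)
        # invert: median R^2 implied by this sigma equals the target
        from scipy.stats import ncf
        lam = 6.2971 ** 2 * ((c - c.mean()) ** 2).sum() / sigma ** 2
        m = float(ncf.median(1, 10, lam))
        assert m / (m + 10) == pytest.approx(0.9313, abs=1e-9)

    def test_unreachable_target_raises(self):
        with pytest.raises(errors.ConfigurationError):
            sigma_for_median_r2(-1.0, 0.01, default_concentration_series())
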