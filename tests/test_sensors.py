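import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vigsa.sensors import (
    band_srf,
    convolve_to_sensor,
    get_sensor,
    list_sensors,
    load_sensor,
    nearest_band_value,
)
from vigsa.vi import builtin_registry, evaluate_vi

GRID = np.arange(400.0, 2501.0)


class TestBandSrf:
    def test_boxcar_equal_weights(self):
        w = band_srf(700.0, 20.0, "boxcar", GRID)
        nz = w[w > 0]
        assert len(nz) == 21
        np.testing.assert_allclose(nz, 1.0 / 21.0)

    def test_gaussian_half_maximum_at_half_fwhm(self):
        w = band_srf(670.0, 20.0, "gaussian", GRID)
        assert w[260] / w[270] == pytest.approx(0.5, rel=1e-9)  # 660 vs 670 nm

    def test_center_outside_range_rejected(self):
        with pytest.raises(ValueError):
            band_srf(3000.0, 20.0, "gaussian", GRID)

    def test_no_support_rejected(self):
        with pytest.raises(ValueError):
            band_srf(2500.0, 10.0, "boxcar", GRID[:500])  # grid ends at 899 nm

    def test_weights_normalized(self):
        for shape in ("gaussian", "boxcar"):
            w = band_srf(1600.0, 60.0, shape, GRID)
            assert w.sum() == pytest.approx(1.0)
            assert w.min() >= 0.0


class TestConvolution:
    def test_flat_spectrum_preserved(self):
        spectra = np.full((3, GRID.size), 0.25)
        view = convolve_to_sensor(GRID, spectra, get_sensor("Landsat8"))
        np.testing.assert_allclose(view.values, 0.25)

    def test_step_spectrum_boxcar_average(self):
        spectrum = np.where(GRID < 700.0, 0.2, 0.4)[None, :]
        from vigsa.sensors import Sensor, SensorBand

        band = Sensor("custom", (SensorBand("b", 700.0, 20.0),))
        view = convolve_to_sensor(GRID, spectrum, band, shape="boxcar")
        # 21 grid points, 10 at 0.2 and 11 at 0.4
        assert view.values[0, 0] == pytest.approx((10 * 0.2 + 11 * 0.4) / 21)

    def test_band_values_within_spectrum_range(self):
        rng = np.random.default_rng(0)
        spectra = 0.1 + 0.6 * rng.random((5, GRID.size))
        for name in list_sensors():
            view = convolve_to_sensor(GRID, spectra, get_sensor(name))
            assert view.values.min() >= spectra.min() - 1e-12
            assert view.values.max() <= spectra.max() + 1e-12

    def test_swir_band_outside_short_grid_rejected(self):
        short_grid = np.arange(400.0, 1021.0)
        spectra = np.full((1, short_grid.size), 0.3)
        with pytest.raises(ValueError):
            convolve_to_sensor(short_grid, spectra, get_sensor("Landsat8"))

    def test_one_nm_boxcar_reproduces_grid_sample(self):
        from vigsa.sensors import Sensor, SensorBand

        rng = np.random.default_rng(1)
        spectrum = rng.random((1, GRID.size))
        sensor = Sensor("narrow", (SensorBand("b", 1205.0, 1.0),))
        view = convolve_to_sensor(GRID, spectrum, sensor, shape="boxcar")
        assert view.values[0, 0] == pytest.approx(spectrum[0, 805])


class TestNearestBandValue:
    def test_fractional_wavelength_snaps_down(self):
        spectrum = GRID[None, :].copy()  # value == wavelength
        assert nearest_band_value(GRID, spectrum, 670.25)[0] == 670.0

    def test_exact_wavelength_returned(self):
        spectrum = GRID[None, :].copy()
        assert nearest_band_value(GRID, spectrum, 1205.0)[0] == 1205.0

    def test_tie_breaks_toward_lower_wavelength(self):
        grid = np.array([500.0, 510.0])
        vals = np.array([[1.0, 2.0]])
        assert nearest_band_value(grid, vals, 505.0)[0] == 1.0

    def test_outside_coverage_rejected(self):
        with pytest.raises(ValueError):
            nearest_band_value(GRID, GRID[None, :], 300.0)


class TestBundledSensors:
    def test_enmap_has_230_bands(self):
        assert len(get_sensor("EnMAP").bands) == 230

    def test_enmap_role_wavelengths(self):
        s = get_sensor("EnMAP")
        expected = {
            "BLUE": 449.25, "GREEN": 527.25, "RED": 670.25,
            "RedEdge": 709.25, "NIR": 1085.0, "SWIR": 2195.0,
        }
        for role, wl in expected.items():
            assert s.band(s.roles[role]).center == pytest.approx(wl)

    def test_all_bands_within_simulated_range(self):
        for name in list_sensors():
            for b in get_sensor(name).bands:
                assert 400.0 <= b.center <= 2500.0

    def test_role_mapping_total_for_registry(self):
        # every index shipped for a sensor must evaluate without missing bands
        rng = np.random.default_rng(2)
        spectra = 0.05 + 0.5 * rng.random((4, GRID.size))
        for name in list_sensors():
            view = convolve_to_sensor(GRID, spectra, get_sensor(name))
            for definition in builtin_registry(name):
                vals = evaluate_vi(definition, view)
                assert vals.shape == (4,)

    def test_load_sensor_csv(self, tmp_path):
        path = tmp_path / "sensor.csv"
        path.write_text("band_name,center_nm,fwhm_nm\nb1,500,10\nb2,800,20\n")
        s = load_sensor(path, name="tiny", roles={"RED": "b1", "NIR": "b2"})
        assert [b.band_name for b in s.bands] == ["b1", "b2"]
        assert s.roles["NIR"] == "b2"

    @settings(derandomize=True, max_examples=20)
    @given(
        center=st.floats(min_value=450, max_value=2400),
        fwhm=st.floats(min_value=2, max_value=200),
    )
    def test_convolution_is_convex_combination(self, center, fwhm):
        w = band_srf(center, fwhm, "gaussian", GRID)
        rng = np.random.default_rng(0)
        s = rng.random(GRID.size)
        v = s @ w
        support = w > 0
        assert s[support].min() - 1e-9 <= v <= s[support].max() + 1e-9
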