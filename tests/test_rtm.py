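import numpy as np
import pytest

from vigsa.rtm import (
    WAVELENGTHS_1NM,
    CanopyParamsINFORM,
    CanopyParamsSAIL,
    LeafParams,
    inform_toc,
    load_coefficients,
    prospect4,
    sail_toc,
    synthetic_coefficients,
    to_5nm_grid,
    toy_canopy,
    toy_specs,
)
from vigsa.rtm.coefficients import write_coefficients


@pytest.fixture(scope="module")
def coeffs():
    return synthetic_coefficients()


class TestProspect4:
    def test_output_grid_and_energy_bounds(self, coeffs):
        r, t = prospect4(LeafParams(1.5, 40.0, 0.01, 0.009), coeffs)
        assert r.shape == t.shape == (2101,)
        assert r.min() >= 0 and t.min() >= 0
        assert np.all(r + t <= 1.0 + 1e-12)

    def test_chlorophyll_darkens_red_reflectance(self, coeffs):
        red = int(670 - 400)
        prev = 1.0
        for cab in (0.0, 20.0, 40.0, 80.0):
            r, _ = prospect4(LeafParams(1.5, cab, 0.01, 0.009), coeffs)
            assert r[red] <= prev + 1e-12
            prev = r[red]

    def test_water_darkens_swir_not_visible(self, coeffs):
        r_dry, _ = prospect4(LeafParams(1.5, 40.0, 0.001, 0.009), coeffs)
        r_wet, _ = prospect4(LeafParams(1.5, 40.0, 0.08, 0.009), coeffs)
        i1940 = int(1940 - 400)
        i550 = int(550 - 400)
        assert r_wet[i1940] < r_dry[i1940] - 0.05
        assert abs(r_wet[i550] - r_dry[i550]) < 0.02

    def test_invalid_parameters_rejected(self, coeffs):
        with pytest.raises(ValueError):
            LeafParams(0.5, 40.0, 0.01, 0.009)
        with pytest.raises(ValueError):
            LeafParams(1.5, -1.0, 0.01, 0.009)

    def test_coefficient_table_roundtrip(self, coeffs, tmp_path):
        path = tmp_path / "coeffs.csv"
        write_coefficients(coeffs, path)
        loaded = load_coefficients(path)
        np.testing.assert_allclose(loaded.k_Cab, coeffs.k_Cab, atol=1e-12)

    def test_checksum_verified(self, coeffs, tmp_path):
        path = tmp_path / "coeffs.csv"
        write_coefficients(coeffs, path)
        with pytest.raises(ValueError, match="checksum"):
            load_coefficients(path, sha256="0" * 64)

    def test_incomplete_table_rejected(self, tmp_path):
        path = tmp_path / "short.csv"
        path.write_text(
            "wavelength_nm,refractive_index,k_Cab,k_Cw,k_Cm\n400,1.5,0.1,0.1,0.1\n"
        )
        with pytest.raises(ValueError):
            load_coefficients(path)


class TestSail:
    def test_bare_soil_limit(self, leaf_rt, soil):
        toc = sail_toc(leaf_rt, CanopyParamsSAIL(LAI=0.0, soil_coeff=0.7, SZA=30), soil)
        np.testing.assert_allclose(toc, 0.7 * soil, atol=1e-12)

    def test_dense_canopy_decouples_soil(self, leaf_rt, soil):
        dark = sail_toc(leaf_rt, CanopyParamsSAIL(LAI=10, soil_coeff=0.0, SZA=30), soil)
        bright = sail_toc(leaf_rt, CanopyParamsSAIL(LAI=10, soil_coeff=1.0, SZA=30), soil)
        vis = slice(0, 300)  # 400-700 nm
        assert np.abs(dark[vis] - bright[vis]).max() < 0.01

    def test_no_scatterers_gives_black_scene(self, soil):
        zero = np.zeros_like(soil)
        toc = sail_toc((zero, zero), CanopyParamsSAIL(LAI=3.0, soil_coeff=0.0, SZA=30), soil)
        np.testing.assert_allclose(toc, 0.0, atol=1e-9)

    def test_reflectance_bounded(self, leaf_rt, soil):
        for lai in (0.2, 2.0, 8.0):
            for lad in (10.0, 57.0, 85.0):
                toc = sail_toc(
                    leaf_rt, CanopyParamsSAIL(LAI=lai, LAD=lad, soil_coeff=1.0, SZA=45),
                    soil,
                )
                assert np.all((toc >= 0) & (toc <= 1)) and np.all(np.isfinite(toc))

    def test_sparse_canopy_brightens_with_soil(self, leaf_rt, soil):
        # at low LAI the soil term dominates, so brightness rises with soil_coeff
        lo = sail_toc(leaf_rt, CanopyParamsSAIL(LAI=0.3, soil_coeff=0.2, SZA=30), soil)
        hi = sail_toc(leaf_rt, CanopyParamsSAIL(LAI=0.3, soil_coeff=0.9, SZA=30), soil)
        assert np.all(hi >= lo - 1e-12)

    def test_grid_mismatch_rejected(self, leaf_rt, soil):
        with pytest.raises(ValueError):
            sail_toc(leaf_rt, CanopyParamsSAIL(LAI=1.0), soil[:100])


class TestInform:
    def test_output_on_5nm_grid(self, leaf_rt, soil):
        toc = inform_toc(
            leaf_rt,
            CanopyParamsINFORM(LAIs=3, LAIu=1, SD=500, H=15, CD=3, SZA=30),
            soil,
        )
        assert toc.shape == (421,)
        assert np.all((toc >= 0) & (toc <= 1))

    def test_vanishing_crowns_approach_understory(self, leaf_rt, soil):
        forest = CanopyParamsINFORM(
            LAIs=3, LAIu=1.5, SD=0.5, H=10, CD=0.1, SZA=30, soil_coeff=0.5
        )
        toc = inform_toc(leaf_rt, forest, soil)
        under = sail_toc(
            leaf_rt, CanopyParamsSAIL(LAI=1.5, soil_coeff=0.5, SZA=30), soil
        )
        assert np.abs(toc - to_5nm_grid(under)).max() < 0.02

    def test_empty_scene_approaches_soil(self, leaf_rt, soil):
        forest = CanopyParamsINFORM(
            LAIs=3, LAIu=0.0, SD=0.5, H=10, CD=0.1, SZA=30, soil_coeff=0.6
        )
        toc = inform_toc(leaf_rt, forest, soil)
        assert np.abs(toc - 0.6 * to_5nm_grid(soil)).max() < 0.02

    def test_crown_cover_saturates(self, leaf_rt, soil):
        # near full cover, extra stems change almost nothing
        a = inform_toc(
            leaf_rt, CanopyParamsINFORM(LAIs=4, LAIu=1, SD=1400, H=20, CD=10, SZA=30),
            soil,
        )
        b = inform_toc(
            leaf_rt, CanopyParamsINFORM(LAIs=4, LAIu=1, SD=1500, H=20, CD=10, SZA=30),
            soil,
        )
        np.testing.assert_allclose(a, b, atol=1e-4)

    def test_block_averaging_is_exact_on_constants(self):
        flat = np.full(2101, 0.42)
        np.testing.assert_allclose(to_5nm_grid(flat), 0.42)


class TestToyModel:
    def test_flat_baseline_at_zero(self):
        s = toy_canopy(np.zeros(3))
        np.testing.assert_allclose(s, 0.5)

    def test_deterministic(self):
        x = np.array([0.3, 0.6, 0.1])
        np.testing.assert_array_equal(toy_canopy(x), toy_canopy(x))

    def test_linear_at_feature_center(self):
        specs = toy_specs(2)
        vals = []
        for x1 in (0.0, 0.5, 1.0):
            s = toy_canopy(np.array([x1, 0.3]), specs=specs)
            vals.append(s[100])  # 500 nm, feature center of parameter 1
        assert vals[0] - vals[1] == pytest.approx(vals[1] - vals[2], abs=1e-12)

    def test_inert_parameter_has_no_effect(self):
        a = toy_canopy(np.array([0.2, 0.9, 0.5]), inert=(1,))
        b = toy_canopy(np.array([0.2, 0.1, 0.5]), inert=(1,))
        np.testing.assert_array_equal(a, b)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            toy_canopy(np.array([1.5, 0.0]))
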