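import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vigsa.sensors import get_sensor
from vigsa.vi import (
    NativeGridView,
    VIDefinition,
    all_indices,
    builtin_registry,
    evaluate_vi,
    expression_symbols,
    get_index,
    parse_vi_expression,
    serialize_expression,
)


def record_view(**symbols):
    """Evaluation view backed by scalar role/wavelength values."""

    class _View:
        def role(self, name):
            return np.array([symbols[name]])

        def rho(self, wl):
            return np.array([symbols[f"rho{int(wl)}"]])

    return _View()


class TestParser:
    def test_role_symbols_collected(self):
        tree = parse_vi_expression("(NIR-RED)/(NIR+RED)")
        roles, wls = expression_symbols(tree)
        assert roles == {"NIR", "RED"} and wls == set()

    def test_wavelength_terms_collected(self):
        tree = parse_vi_expression("2*rho(1205)/(rho(1095)+rho(1275))")
        roles, wls = expression_symbols(tree)
        assert roles == set() and wls == {1205.0, 1095.0, 1275.0}

    def test_syntax_error_with_position(self):
        with pytest.raises(SyntaxError):
            parse_vi_expression("(NIR-")

    def test_unknown_symbol_rejected(self):
        with pytest.raises(SyntaxError):
            parse_vi_expression("NIR + PURPLE")

    def test_empty_rejected(self):
        with pytest.raises(SyntaxError):
            parse_vi_expression("   ")

    def test_power_right_associative(self):
        tree = parse_vi_expression("GREEN^2")
        assert tree == ("^", ("role", "GREEN"), ("num", 2.0))

    @pytest.mark.parametrize("definition", all_indices(), ids=lambda d: d.abbreviation)
    def test_shipped_expressions_round_trip(self, definition):
        tree = definition.tree
        text = serialize_expression(tree)
        assert parse_vi_expression(text) == tree


class TestEvaluation:
    def test_ndvi_arithmetic(self):
        v = evaluate_vi(get_index("NDVI"), record_view(NIR=0.5, RED=0.1))
        assert v[0] == pytest.approx(0.4 / 0.6)

    def test_ndvi_symmetry_zero(self):
        v = evaluate_vi(get_index("NDVI"), record_view(NIR=0.3, RED=0.3))
        assert v[0] == pytest.approx(0.0)

    def test_ndwi_arithmetic(self):
        v = evaluate_vi(get_index("NDWI"), record_view(rho860=0.4, rho1240=0.2))
        assert v[0] == pytest.approx(0.2 / 0.6)

    def test_evi_arithmetic(self):
        v = evaluate_vi(get_index("EVI"), record_view(NIR=0.4, RED=0.1, BLUE=0.05))
        assert v[0] == pytest.approx(2.5 * 0.3 / (0.4 + 0.6 - 0.375 + 1.0))

    def test_guarded_denominator_yields_nan(self):
        v = evaluate_vi(get_index("GRVI"), record_view(NIR=0.5, GREEN=0.0))
        assert np.isnan(v[0])

    def test_missing_symbol_raises(self):
        with pytest.raises(KeyError):
            evaluate_vi(
                get_index("NDVI"),
                NativeGridView(np.arange(400.0, 500.0), np.ones((1, 100)),
                               role_wavelengths={"RED": 450.0}),
            )

    @settings(derandomize=True, max_examples=50)
    @given(
        a=st.floats(min_value=1e-6, max_value=1.0),
        b=st.floats(min_value=1e-6, max_value=1.0),
    )
    def test_normalized_difference_bounded(self, a, b):
        for abbr, kw in [
            ("NDVI", dict(NIR=a, RED=b)),
            ("GNDVI", dict(NIR=a, GREEN=b)),
            ("NDWI", dict(rho860=a, rho1240=b)),
            ("SIWSI", dict(rho800=a, rho1640=b)),
        ]:
            v = evaluate_vi(get_index(abbr), record_view(**kw))[0]
            if np.isfinite(v):
                assert -1.0 - 1e-9 <= v <= 1.0 + 1e-9


class TestRegistry:
    def test_rededge_index_availability(self):
        s2 = [d.abbreviation for d in builtin_registry("Sentinel2")]
        l8 = [d.abbreviation for d in builtin_registry("Landsat8")]
        assert "CIrededge" in s2 and "CIrededge" not in l8

    def test_ndwi_needs_1240nm_band(self):
        modis = [d.abbreviation for d in builtin_registry("MODIS")]
        l8 = [d.abbreviation for d in builtin_registry("Landsat8")]
        assert "NDWI" in modis and "NDWI" not in l8

    def test_enmap_full_index_set(self):
        defs = builtin_registry("EnMAP")
        by_target = {}
        for d in defs:
            by_target.setdefault(d.target_variable, []).append(d.abbreviation)
        assert len(by_target["LCC"]) == 13
        assert len(by_target["LWC"]) == 14
        assert len(by_target["LAI"]) == 9

    def test_unknown_sensor_and_index_rejected(self):
        with pytest.raises(KeyError):
            builtin_registry("ASTER")
        with pytest.raises(KeyError):
            get_index("NOPE")

    def test_out_of_scope_sensor_not_offered(self):
        # a Landsat 8 run must not silently approximate a 1240 nm band
        assert all(
            d.abbreviation != "NDWI" for d in builtin_registry("Landsat8")
        )

    def test_user_defined_expression(self):
        d = VIDefinition(
            name="custom", abbreviation="custom",
            expression="sqrt(abs(NIR-RED))", target_variable="user",
        )
        v = evaluate_vi(d, record_view(NIR=0.09, RED=0.05))
        assert v[0] == pytest.approx(0.2)


class TestNativeGridView:
    def test_role_resolution_via_default_wavelengths(self):
        grid = np.arange(400.0, 2501.0)
        spectra = np.tile(grid, (2, 1))  # value == wavelength
        view = NativeGridView(grid, spectra)
        assert view.role("RED")[0] == 665.0
        assert view.rho(670.25)[0] == 670.0
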