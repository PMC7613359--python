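import numpy as np
import pytest

from vigsa.benchmarks import make_benchmark
from vigsa.gsa import (
    convergence_scan,
    estimate_output_moments,
    estimate_sobol_indices,
    normalize_total_effects,
)
from vigsa.sampling import generate_unit_design, scale_design


def saltelli(name, N, params=None, scheme="uniform-sobol", seed=None):
    f, rec = make_benchmark(name, params)
    d = generate_unit_design(rec.k, N, scheme=scheme, seed=seed)
    specs = list(rec.specs)
    out = lambda M: f(scale_design(M, specs))
    res = estimate_sobol_indices(
        out(d.P), out(d.Q), [out(M) for M in d.radial],
        variable_names=[s.name for s in specs], output_name=name,
    )
    return res, rec


class TestOutputMoments:
    def test_constant_output(self):
        f0, V = estimate_output_moments(np.full(100, 3.7))
        assert f0 == pytest.approx(3.7)
        assert V == pytest.approx(0.0, abs=1e-12)

    def test_two_point_output(self):
        f0, V = estimate_output_moments(np.array([0.0, 1.0]))
        assert (f0, V) == (pytest.approx(0.5), pytest.approx(0.25))

    def test_uniform_variance_recovered(self):
        d = generate_unit_design(k=1, N=2**14)
        f0, V = estimate_output_moments(d.P[:, 0])
        se = np.sqrt(1.0 / 180.0 / 2**14)  # var of U(0,1)^2 moments, rough
        assert abs(V - 1.0 / 12.0) < 3 * max(se, 1e-3)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            estimate_output_moments(np.array([1.0]))
        with pytest.raises(ValueError):
            estimate_output_moments(np.array([1.0, np.nan]))


class TestSobolEstimator:
    def test_additive_linear_closed_form(self):
        res, rec = saltelli("additive_linear", 2**13, {"coefficients": (1.0, 2.0)})
        np.testing.assert_allclose(res.Si, [0.2, 0.8], atol=0.02)
        np.testing.assert_allclose(res.STi, [0.2, 0.8], atol=0.02)

    def test_ishigami_closed_form(self):
        res, rec = saltelli("ishigami", 2**14)
        np.testing.assert_allclose(res.Si, rec.closed_form_Si, atol=0.02)
        np.testing.assert_allclose(res.STi, rec.closed_form_STi, atol=0.02)

    def test_constant_model_degenerate(self):
        res, _ = saltelli("constant", 256)
        assert res.degenerate
        assert np.all(res.Si == 0) and np.all(res.STi == 0)

    def test_total_effect_dominates_first_order(self):
        # STi >= Si up to Monte Carlo noise, here generously 3 standard errors
        for name in ("ishigami", "g_function", "additive_linear"):
            res, _ = saltelli(name, 2**12)
            assert np.all(res.STi_raw - res.Si_raw > -3.0 / np.sqrt(2**12))

    def test_first_order_sum_bounded(self):
        for name in ("ishigami", "g_function"):
            res, _ = saltelli(name, 2**12)
            assert res.Si.sum() <= 1.0 + 0.05

    def test_additive_model_has_no_interactions(self):
        res, _ = saltelli("additive_linear", 2**13, {"coefficients": (1.0, 2.0, 3.0)})
        assert np.all(np.abs(res.STi_raw - res.Si_raw) < 3.0 / np.sqrt(2**13))
        assert res.Si.sum() == pytest.approx(1.0, abs=0.03)

    def test_dummy_variable_gets_zero(self):
        res, _ = saltelli("dummy_variable", 2**12)
        assert res.Si[2] < 0.01 and res.STi[2] < 0.01

    def test_nan_rows_excluded_jointly(self):
        rng = np.random.default_rng(0)
        fP, fQ = rng.random(100), rng.random(100)
        fR = [rng.random(100), rng.random(100)]
        fR[0][3] = np.nan
        res = estimate_sobol_indices(fP, fQ, fR)
        assert res.N == 99 and res.n_excluded_rows == 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            estimate_sobol_indices(np.ones(4), np.ones(5), [np.ones(4)])


class TestNormalizeTotalEffects:
    def test_already_normalized_passthrough(self):
        res, _ = saltelli("additive_linear", 2**10)
        shares = normalize_total_effects(res)
        assert shares.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(shares, res.STi / res.STi.sum())

    def test_degenerate_rejected(self):
        res, _ = saltelli("constant", 128)
        with pytest.raises(ValueError):
            normalize_total_effects(res)


class TestConvergenceScan:
    def test_ishigami_error_shrinks_with_n(self):
        f, rec = make_benchmark("ishigami")
        table = convergence_scan(f, list(rec.specs), [64, 256, 1024, 4096])
        ref = table[table.N == 4096].set_index("variable")["STi"]
        errs = [
            np.abs(
                table[table.N == n].set_index("variable")["STi"] - ref
            ).max()
            for n in (64, 256, 1024)
        ]
        assert errs[2] < errs[0]

    def test_constant_model_all_zero(self):
        f, rec = make_benchmark("constant")
        table = convergence_scan(f, list(rec.specs), [16, 64])
        assert (table.STi == 0).all() and table.degenerate.all()

    def test_single_point_grid_shape(self):
        f, rec = make_benchmark("additive_linear")
        table = convergence_scan(f, list(rec.specs), [128])
        assert len(table) == rec.k

    def test_non_increasing_grid_rejected(self):
        f, rec = make_benchmark("additive_linear")
        with pytest.raises(ValueError):
            convergence_scan(f, list(rec.specs), [64, 64])
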