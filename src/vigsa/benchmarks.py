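"""Analytic benchmark functions with known Sobol' indices.

These make the estimator machinery testable without any radiative-transfer
data: each benchmark ships its closed-form first-order and total-effect
indices, and :func:`double_loop_oracle` provides a brute-force
conditional-variance estimate that is independent of the Saltelli/radial
estimator path (it uses plain pseudo-random sampling, so the two estimators'
Monte Carlo errors are uncorrelated).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .sampling import VariableSpec

__all__ = ["AnalyticBenchmark", "make_benchmark", "double_loop_oracle"]


@dataclass(frozen=True)
class AnalyticBenchmark:
    name: str
    k: int
    closed_form_Si: np.ndarray
    closed_form_STi: np.ndarray
    specs: tuple[VariableSpec, ...]


def _unit_specs(k: int, lo: float = 0.0, hi: float = 1.0) -> tuple[VariableSpec, ...]:
    return tuple(VariableSpec(f"x{i + 1}", lo, hi) for i in range(k))


def make_benchmark(
    name: str, params: dict | None = None
) -> tuple[Callable[[np.ndarray], np.ndarray], AnalyticBenchmark]:
    """Return ``(function, record)`` for a named benchmark.

    The function maps an (n, k) matrix of *physical* inputs (within the
    record's variable bounds) to a length-n output vector.

    Benchmarks
    ----------
    additive_linear : f = sum b_i x_i on [0,1]^k; params {"coefficients"}.
        V_i = b_i^2 / 12, no interactions.
    ishigami : f = sin x1 + a sin^2 x2 + b x3^4 sin x1 on [-pi, pi]^3;
        params {"a": 7, "b": 0.1}.  x3 acts only through its interaction
        with x1 (S3 = 0, ST3 > 0).
    g_function : Sobol' g-function on [0,1]^k; params {"a"} (default
        (0, 1, 4.5, 9)).
    constant : f = c on [0,1]^3; all indices zero.
    dummy_variable : f = x1 + 2 x2 on [0,1]^3; x3 is inert.
    """
    params = dict(params or {})

    if name == "additive_linear":
        b = np.asarray(params.get("coefficients", (1.0, 2.0)), dtype=float)
        k = b.size
        Vi = b**2 / 12.0
        Si = Vi / Vi.sum()

        def f(x: np.ndarray) -> np.ndarray:
            return np.asarray(x, dtype=float) @ b

        return f, AnalyticBenchmark(name, k, Si, Si.copy(), _unit_specs(k))

    if name == "ishigami":
        a = float(params.get("a", 7.0))
        bb = float(params.get("b", 0.1))
        pi = np.pi
        V1 = 0.5 * (1.0 + bb * pi**4 / 5.0) ** 2
        V2 = a**2 / 8.0
        V13 = 8.0 * bb**2 * pi**8 / 225.0
        V = V1 + V2 + V13
        Si = np.array([V1 / V, V2 / V, 0.0])
        STi = np.array([(V1 + V13) / V, V2 / V, V13 / V])

        def f(x: np.ndarray) -> np.ndarray:
            x = np.asarray(x, dtype=float)
            return (
                np.sin(x[:, 0])
                + a * np.sin(x[:, 1]) ** 2
                + bb * x[:, 2] ** 4 * np.sin(x[:, 0])
            )

        return f, AnalyticBenchmark(name, 3, Si, STi, _unit_specs(3, -pi, pi))

    if name == "g_function":
        a = np.asarray(params.get("a", (0.0, 1.0, 4.5, 9.0)), dtype=float)
        k = a.size
        Vi = (1.0 / 3.0) / (1.0 + a) ** 2
        V = np.prod(1.0 + Vi) - 1.0
        Si = Vi / V
        STi = np.array(
            [Vi[i] * np.prod(np.delete(1.0 + Vi, i)) / V for i in range(k)]
        )

        def f(x: np.ndarray) -> np.ndarray:
            x = np.asarray(x, dtype=float)
            return np.prod((np.abs(4.0 * x - 2.0) + a) / (1.0 + a), axis=1)

        return f, AnalyticBenchmark(name, k, Si, STi, _unit_specs(k))

    if name == "constant":
        c = float(params.get("c", 3.0))
        zeros = np.zeros(3)

        def f(x: np.ndarray) -> np.ndarray:
            return np.full(np.asarray(x).shape[0], c)

        return f, AnalyticBenchmark(name, 3, zeros, zeros.copy(), _unit_specs(3))

    if name == "dummy_variable":
        Si = np.array([1.0 / 5.0, 4.0 / 5.0, 0.0])

        def f(x: np.ndarray) -> np.ndarray:
            x = np.asarray(x, dtype=float)
            return x[:, 0] + 2.0 * x[:, 1]

        return f, AnalyticBenchmark(name, 3, Si, Si.copy(), _unit_specs(3))

    raise ValueError(f"unknown benchmark {name!r}")


def double_loop_oracle(
    function: Callable[[np.ndarray], np.ndarray],
    specs: list[VariableSpec],
    n_outer: int = 4096,
    n_inner: int = 32,
    seed: int | None = None,
) -> np.ndarray:
    """First-order indices by brute-force conditional expectation.

    For each variable i, ``n_outer`` values of x_i are drawn; at each, the
    conditional mean of the output over ``n_inner`` fresh draws of the other
    variables is computed.  Si is the variance of those conditional means
    (minus the standard inner-noise bias term, mean inner variance over
    ``n_inner``) over the unconditional variance.  Test-only cross-check;
    intentionally slow and restricted to small problems.
    """
    k = len(specs)
    if k > 4:
        raise ValueError("double-loop oracle is restricted to k <= 4")
    if n_outer * n_inner * k > 4_000_000:
        raise ValueError("double-loop oracle budget exceeded")
    rng = np.random.default_rng(seed)
    lo = np.array([s.min for s in specs])
    hi = np.array([s.max for s in specs])

    base = lo + rng.random((n_outer * n_inner, k)) * (hi - lo)
    f_all = np.asarray(function(base), dtype=float)
    V = f_all.var()
    if V <= 0.0:
        return np.zeros(k)

    Si = np.empty(k)
    for i in range(k):
        xi = lo[i] + rng.random(n_outer) * (hi[i] - lo[i])
        x = lo + rng.random((n_outer, n_inner, k)) * (hi - lo)
        x[:, :, i] = xi[:, None]
        fx = np.asarray(function(x.reshape(-1, k)), dtype=float).reshape(
            n_outer, n_inner
        )
        cond_means = fx.mean(axis=1)
        inner_var = fx.var(axis=1, ddof=1).mean() if n_inner > 1 else 0.0
        Si[i] = max(cond_means.var() - inner_var / n_inner, 0.0) / V
    return Si
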