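"""Closed-form toy canopy model for tests and pipeline dry-runs.

The spectrum is a flat baseline minus one Gaussian absorption feature per
parameter, linear in each (bound-normalized) parameter at its feature
center.  It needs no coefficient data, making the full sampling -> model ->
sensor -> index -> estimator chain testable with known analytic sensitivity
structure.
"""

from __future__ import annotations

import numpy as np

from ..sampling import VariableSpec
from .coefficients import WAVELENGTHS_1NM

__all__ = ["toy_canopy", "toy_specs", "toy_feature_centers"]

BASELINE = 0.5
FEATURE_SIGMA = 40.0
FEATURE_AMPLITUDE = 0.35


def toy_feature_centers(p: int) -> np.ndarray:
    """Absorption feature centers (nm) for a p-parameter toy model."""
    return np.linspace(500.0, 2300.0, p)


def toy_specs(p: int = 3) -> list[VariableSpec]:
    """Unit-interval variable specs for a p-parameter toy model."""
    if p < 2:
        raise ValueError("toy model needs at least 2 parameters")
    return [VariableSpec(f"t{i + 1}", 0.0, 1.0) for i in range(p)]


def toy_canopy(
    params: np.ndarray,
    specs: list[VariableSpec] | None = None,
    inert: tuple[int, ...] = (),
    wavelengths: np.ndarray | None = None,
) -> np.ndarray:
    """Deterministic toy spectrum for one parameter vector or an (n, p) batch.

    Parameters are normalized to [0, 1] with ``specs`` bounds (unit bounds if
    omitted).  Indices listed in ``inert`` contribute nothing, giving exact
    dummy variables.  All parameters at their minimum yield the flat
    baseline.
    """
    wl = WAVELENGTHS_1NM if wavelengths is None else np.asarray(wavelengths, float)
    x = np.atleast_2d(np.asarray(params, dtype=float))
    p = x.shape[1]
    if p < 2:
        raise ValueError("toy model needs at least 2 parameters")
    if specs is not None:
        lo = np.array([s.min for s in specs])
        hi = np.array([s.max for s in specs])
        x = (x - lo) / (hi - lo)
    if np.any((x < -1e-9) | (x > 1 + 1e-9)):
        raise ValueError("toy parameters outside their declared bounds")

    centers = toy_feature_centers(p)
    weights = FEATURE_AMPLITUDE * np.exp(
        -0.5 * ((wl[None, :] - centers[:, None]) / FEATURE_SIGMA) ** 2
    )  # (p, n_wl)
    if inert:
        weights = weights.copy()
        weights[list(inert), :] = 0.0
    spectra = BASELINE - x @ weights
    out = np.clip(spectra, 0.0, 1.0)
    return out[0] if np.asarray(params).ndim == 1 else out
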