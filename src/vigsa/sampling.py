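"""Quasi-random sampling designs for variance-based sensitivity analysis.

The Saltelli/Jansen estimators used here require two independent N x k base
matrices ``P`` and ``Q`` on the unit hypercube plus k "radial" recombination
matrices, where the i-th radial matrix equals ``P`` with its i-th column
replaced by the i-th column of ``Q``.  Evaluating the model on P, Q and the k
radial blocks costs exactly ``N * (k + 2)`` runs.

The default design draws an ``N x 2k`` low-discrepancy Sobol' matrix and
splits it into left (P) and right (Q) halves.  The initial all-zeros Sobol'
point is skipped so that the default, unscrambled design is reproducible
without a seed; the seed only matters for the pseudo-random and
Latin-hypercube schemes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import qmc

__all__ = [
    "VariableSpec",
    "DesignMatrices",
    "SCHEMES",
    "generate_unit_design",
    "radial_matrices",
    "scale_design",
]

SCHEMES = ("uniform-sobol", "uniform-random", "latin-hypercube")


@dataclass(frozen=True)
class VariableSpec:
    """One model input variable with physical bounds.

    Parameters
    ----------
    name : str
        Identifier, unique within a model's variable list.
    min, max : float
        Physical bounds; samples are drawn uniformly on ``[min, max]``.
    unit : str
        Unit label, for reporting only.
    distribution : str
        Sampling scheme tag, one of :data:`SCHEMES`.
    """

    name: str
    min: float
    max: float
    unit: str = "-"
    distribution: str = "uniform-sobol"

    def __post_init__(self) -> None:
        if not np.isfinite(self.min) or not np.isfinite(self.max):
            raise ValueError(f"{self.name}: bounds must be finite")
        if self.min >= self.max:
            raise ValueError(f"{self.name}: min ({self.min}) must be < max ({self.max})")


@dataclass
class DesignMatrices:
    """Unit-hypercube design: base matrices P, Q and the k radial blocks."""

    P: np.ndarray
    Q: np.ndarray
    radial: list[np.ndarray] = field(default_factory=list)

    @property
    def N(self) -> int:
        return self.P.shape[0]

    @property
    def k(self) -> int:
        return self.P.shape[1]

    @property
    def n_model_runs(self) -> int:
        """Total model evaluations implied by the full scheme: N * (k + 2)."""
        return self.N * (self.k + 2)


def generate_unit_design(
    k: int, N: int, scheme: str = "uniform-sobol", seed: int | None = None
) -> DesignMatrices:
    """Build P, Q and radial matrices on the k-dimensional unit hypercube.

    An ``N x 2k`` sample is drawn with the requested scheme; ``P`` is its left
    and ``Q`` its right k columns.  Identical ``(k, N, scheme, seed)`` yield
    bitwise-identical output.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if N < 2:
        raise ValueError(f"N must be >= 2, got {N}")
    if scheme not in SCHEMES:
        raise ValueError(f"unsupported scheme {scheme!r}; expected one of {SCHEMES}")

    if scheme == "uniform-sobol":
        # Unscrambled Sobol'; skip the all-zeros first point.
        sampler = qmc.Sobol(d=2 * k, scramble=False)
        sampler.fast_forward(1)
        block = sampler.random(N)
    elif scheme == "latin-hypercube":
        sampler = qmc.LatinHypercube(d=2 * k, rng=np.random.default_rng(seed))
        block = sampler.random(N)
    else:  # uniform-random
        rng = np.random.default_rng(seed)
        block = rng.random((N, 2 * k))

    P = np.ascontiguousarray(block[:, :k])
    Q = np.ascontiguousarray(block[:, k:])
    return DesignMatrices(P=P, Q=Q, radial=radial_matrices(P, Q))


def radial_matrices(P: np.ndarray, Q: np.ndarray) -> list[np.ndarray]:
    """Return the k matrices ``PQ(i)``: P with column i taken from Q."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise ValueError(f"shape mismatch: P {P.shape} vs Q {Q.shape}")
    out = []
    for i in range(P.shape[1]):
        M = P.copy()
        M[:, i] = Q[:, i]
        out.append(M)
    return out


def scale_design(unit: np.ndarray, specs: list[VariableSpec]) -> np.ndarray:
    """Map a unit-hypercube matrix column-wise onto physical variable bounds."""
    unit = np.asarray(unit, dtype=float)
    if unit.ndim != 2 or unit.shape[1] != len(specs):
        raise ValueError(
            f"column count {unit.shape[-1] if unit.ndim == 2 else '?'} does not "
            f"match the {len(specs)} variable specs"
        )
    lo = np.array([s.min for s in specs])
    hi = np.array([s.max for s in specs])
    return lo + unit * (hi - lo)
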