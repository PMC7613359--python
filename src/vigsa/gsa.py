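"""Monte Carlo estimators of Sobol' first-order and total-effect indices.

Given model outputs on the base matrices P and Q and on the k radial blocks
``PQ(i)`` (P with column i from Q), the estimators are

    f0_hat = mean(f(P))
    V_hat  = mean(f(P)^2) - f0_hat^2
    Si_hat  = (1/N) sum_j f(Q)_j * (f(PQ(i))_j - f(P)_j)  / V_hat
    STi_hat = (1/2N) sum_j (f(P)_j - f(PQ(i))_j)^2        / V_hat

Si measures the variance fraction a single input drives on its own; STi adds
every interaction the input takes part in, so STi >= Si up to Monte Carlo
noise.  Finite-N estimates of Si can be slightly negative; raw values are
kept and clipped copies reported.

Rows whose output is not finite in any of the paired vectors (e.g. a
vegetation index with a vanishing denominator) are removed from *all* blocks
jointly, keeping the row pairing the estimators rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sampling import VariableSpec, generate_unit_design, scale_design

__all__ = [
    "GSAResult",
    "estimate_output_moments",
    "estimate_sobol_indices",
    "normalize_total_effects",
    "convergence_scan",
]

#: V_hat below this times max(1, f0_hat^2) marks a degenerate (constant) output.
DEGENERATE_VARIANCE_REL = 1e-12


@dataclass
class GSAResult:
    """Sobol' index estimates for one scalar model output."""

    variable_names: list[str]
    Si: np.ndarray            # clipped to [0, inf)
    STi: np.ndarray           # clipped to [0, inf)
    Si_raw: np.ndarray
    STi_raw: np.ndarray
    f0_hat: float
    V_hat: float
    N: int
    degenerate: bool = False
    n_excluded_rows: int = 0
    output_name: str = ""

    @property
    def k(self) -> int:
        return len(self.variable_names)

    def sti_shares(self) -> np.ndarray:
        """Total-effect indices normalized to sum to one (see
        :func:`normalize_total_effects`)."""
        return normalize_total_effects(self)

    def to_frame(self) -> pd.DataFrame:
        """One row per variable, in the result-CSV schema."""
        shares = (
            self.sti_shares()
            if not self.degenerate and self.STi.sum() > 0
            else np.zeros(self.k)
        )
        return pd.DataFrame(
            {
                "output_name": self.output_name,
                "variable": self.variable_names,
                "Si_raw": self.Si_raw,
                "Si": self.Si,
                "STi_raw": self.STi_raw,
                "STi": self.STi,
                "STi_share": shares,
                "N": self.N,
                "degenerate": self.degenerate,
            }
        )


def estimate_output_moments(fP: np.ndarray) -> tuple[float, float]:
    """Mean and unconditional variance of the output from the P-block runs.

    Negative variance from floating-point cancellation is clamped to zero.
    """
    fP = np.asarray(fP, dtype=float)
    if fP.size < 2:
        raise ValueError("need at least two model outputs")
    if not np.all(np.isfinite(fP)):
        raise ValueError("non-finite model outputs")
    f0_hat = float(fP.mean())
    V_hat = float(np.mean(fP**2) - f0_hat**2)
    return f0_hat, max(V_hat, 0.0)


def _drop_invalid_rows(
    fP: np.ndarray, fQ: np.ndarray, fR: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray, list[np.ndarray], int]:
    stacked = np.vstack([fP, fQ, *fR])
    ok = np.all(np.isfinite(stacked), axis=0)
    n_bad = int((~ok).sum())
    if n_bad == 0:
        return fP, fQ, fR, 0
    return fP[ok], fQ[ok], [r[ok] for r in fR], n_bad


def estimate_sobol_indices(
    fP: np.ndarray,
    fQ: np.ndarray,
    fR: list[np.ndarray],
    variable_names: list[str] | None = None,
    output_name: str = "",
) -> GSAResult:
    """Estimate Si and STi from the paired P/Q/radial model outputs.

    ``fR[i]`` holds the outputs on the radial block where variable i was
    resampled.  All vectors must share the base sample length N; rows with a
    non-finite value anywhere are excluded jointly.
    """
    fP = np.asarray(fP, dtype=float).ravel()
    fQ = np.asarray(fQ, dtype=float).ravel()
    fR = [np.asarray(r, dtype=float).ravel() for r in fR]
    k = len(fR)
    if k < 1:
        raise ValueError("need at least one radial output vector")
    if variable_names is None:
        variable_names = [f"x{i + 1}" for i in range(k)]
    if len(variable_names) != k:
        raise ValueError("variable_names length does not match radial list")
    for v in (fQ, *fR):
        if v.shape != fP.shape:
            raise ValueError("all output vectors must have the same length N")

    fP, fQ, fR, n_bad = _drop_invalid_rows(fP, fQ, fR)
    if fP.size < 2:
        raise ValueError("fewer than two valid rows after exclusion")
    N = fP.size

    f0_hat, V_hat = estimate_output_moments(fP)
    R = np.vstack(fR)  # k x N

    if V_hat < DEGENERATE_VARIANCE_REL * max(1.0, f0_hat**2):
        zeros = np.zeros(k)
        return GSAResult(
            variable_names=list(variable_names),
            Si=zeros.copy(), STi=zeros.copy(),
            Si_raw=zeros.copy(), STi_raw=zeros.copy(),
            f0_hat=f0_hat, V_hat=V_hat, N=N,
            degenerate=True, n_excluded_rows=n_bad, output_name=output_name,
        )

    Si_raw = (R - fP) @ fQ / (N * V_hat)
    STi_raw = np.sum((fP - R) ** 2, axis=1) / (2.0 * N * V_hat)
    return GSAResult(
        variable_names=list(variable_names),
        Si=np.clip(Si_raw, 0.0, None),
        STi=np.clip(STi_raw, 0.0, None),
        Si_raw=Si_raw,
        STi_raw=STi_raw,
        f0_hat=f0_hat,
        V_hat=V_hat,
        N=N,
        degenerate=False,
        n_excluded_rows=n_bad,
        output_name=output_name,
    )


def normalize_total_effects(result: GSAResult) -> np.ndarray:
    """Total-effect indices rescaled to sum to one.

    STi values need not sum to one (interactions are counted once per
    participant), so "variable i drives X % of the index's variability"
    statements use these shares.
    """
    if result.degenerate:
        raise ValueError("degenerate result: output variance is zero")
    total = float(result.STi.sum())
    if total <= 0.0:
        raise ValueError("degenerate result: all total-effect indices are zero")
    return result.STi / total


def convergence_scan(
    model,
    specs: list[VariableSpec],
    N_grid: list[int],
    scheme: str = "uniform-sobol",
    seed: int | None = None,
    output_name: str = "",
) -> pd.DataFrame:
    """Total-effect trajectories over increasing sample counts.

    The design is built once at ``max(N_grid)`` and the estimators are applied
    to its leading-N prefixes, which for the nested Sobol' sequence is the
    design one would have drawn at the smaller N.  ``model`` maps a physical
    (n x k) matrix to an output vector of length n.

    Returns a long table with one row per (N, variable).
    """
    N_grid = list(N_grid)
    if any(b <= a for a, b in zip(N_grid, N_grid[1:])):
        raise ValueError("N_grid must be strictly increasing")
    k = len(specs)
    design = generate_unit_design(k, N_grid[-1], scheme=scheme, seed=seed)

    def run(unit_block: np.ndarray) -> np.ndarray:
        return np.asarray(model(scale_design(unit_block, specs)), dtype=float)

    fP = run(design.P)
    fQ = run(design.Q)
    fR = [run(M) for M in design.radial]

    rows = []
    for N in N_grid:
        res = estimate_sobol_indices(
            fP[:N], fQ[:N], [r[:N] for r in fR],
            variable_names=[s.name for s in specs],
            output_name=output_name,
        )
        for name, si, sti in zip(res.variable_names, res.Si, res.STi):
            rows.append(
                {"output_name": output_name, "N": N, "variable": name,
                 "Si": si, "STi": sti, "degenerate": res.degenerate}
            )
    return pd.DataFrame(rows)
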