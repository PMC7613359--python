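"""PROSPECT-4 leaf optical properties model.

The leaf is represented as a stack of ``N`` homogeneous absorbing plates
with rough surfaces.  Per wavelength, the absorption coefficient of one
elementary plate is the mixture of the chlorophyll a+b, water and dry-matter
specific absorption coefficients weighted by their contents and divided by
the structure parameter ``N``; plate transmissivity follows from the
exponential-integral solution for an absorbing slab, surface reflectance
from the average transmissivity of the air/leaf interface (Stern's formula),
and the N-plate stack from the Stokes doubling relations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import exp1

from .coefficients import SpectralCoefficients

__all__ = ["LeafParams", "prospect4"]


@dataclass(frozen=True)
class LeafParams:
    """PROSPECT-4 inputs.

    N_struct : leaf structure parameter (number of elementary plates, >= 1)
    Cab : chlorophyll a+b content, ug/cm^2
    Cw : equivalent water thickness, cm
    Cm : dry matter content, g/cm^2
    """

    N_struct: float
    Cab: float
    Cw: float
    Cm: float

    def __post_init__(self) -> None:
        if self.N_struct < 1.0:
            raise ValueError(f"N_struct must be >= 1, got {self.N_struct}")
        if min(self.Cab, self.Cw, self.Cm) < 0.0:
            raise ValueError("leaf constituent contents must be nonnegative")


def tav(theta_deg: float, n: np.ndarray) -> np.ndarray:
    """Average transmissivity of a dielectric interface for isotropic light
    within a cone of half-angle ``theta_deg`` (Stern's analytic solution)."""
    n = np.asarray(n, dtype=float)
    if theta_deg == 0.0:
        return 4.0 * n / (n + 1.0) ** 2

    theta = np.radians(theta_deg)
    n2 = n**2
    npx = n2 + 1.0
    nm = n2 - 1.0
    a = (n + 1.0) ** 2 / 2.0
    k = -((n2 - 1.0) ** 2) / 4.0
    ds = np.sin(theta)
    ds2 = ds**2

    if theta_deg == 90.0:
        b1 = np.zeros_like(n)
    else:
        b1 = np.sqrt((ds2 - npx / 2.0) ** 2 + k)
    b2 = ds2 - npx / 2.0
    b = b1 - b2
    b3 = b**3
    a3 = a**3

    ts = (k**2 / (6.0 * b3) + k / b - b / 2.0) - (
        k**2 / (6.0 * a3) + k / a - a / 2.0
    )
    tp1 = -2.0 * n2 * (b - a) / npx**2
    tp2 = -2.0 * n2 * npx * np.log(b / a) / nm**2
    tp3 = n2 * (1.0 / b - 1.0 / a) / 2.0
    tp4 = (
        16.0 * n2**2 * (n2**2 + 1.0)
        * np.log((2.0 * npx * b - nm**2) / (2.0 * npx * a - nm**2))
        / (npx**3 * nm**2)
    )
    tp5 = (
        16.0 * n2**3
        * (1.0 / (2.0 * npx * b - nm**2) - 1.0 / (2.0 * npx * a - nm**2))
        / npx**3
    )
    tp = tp1 + tp2 + tp3 + tp4 + tp5
    return (ts + tp) / (2.0 * ds2)


def _plate_transmissivity(kappa: np.ndarray) -> np.ndarray:
    """Transmissivity of one elementary absorbing plate with absorption
    coefficient ``kappa``: (1-k)exp(-k) + k^2 E1(k), equal to 1 at k = 0."""
    tau = np.ones_like(kappa)
    pos = kappa > 0.0
    kp = kappa[pos]
    tau[pos] = (1.0 - kp) * np.exp(-kp) + kp**2 * exp1(kp)
    return np.clip(tau, 0.0, 1.0)


def prospect4(
    leaf: LeafParams, coeffs: SpectralCoefficients, alpha: float = 40.0
) -> tuple[np.ndarray, np.ndarray]:
    """Leaf directional-hemispherical reflectance and transmittance.

    Returns ``(reflectance, transmittance)`` on the 1-nm grid (length 2101);
    both lie in [0, 1] and their sum never exceeds 1.  ``alpha`` is the
    maximum incidence angle describing surface roughness of the top
    interface (40 degrees in the standard calibration).
    """
    n = coeffs.refractive_index
    kappa = (
        leaf.Cab * coeffs.k_Cab + leaf.Cw * coeffs.k_Cw + leaf.Cm * coeffs.k_Cm
    ) / leaf.N_struct
    theta = _plate_transmissivity(kappa)

    # interface transmissivities
    talf = tav(alpha, n)
    ralf = 1.0 - talf
    t12 = tav(90.0, n)
    r12 = 1.0 - t12
    t21 = t12 / n**2
    r21 = 1.0 - t21

    # top surface side (oblique incidence on the first plate)
    denom = 1.0 - r21**2 * theta**2
    Ta = talf * theta * t21 / denom
    Ra = ralf + r21 * theta * Ta

    # diffuse fluxes inside the stack (isotropic incidence)
    t = t12 * theta * t21 / denom
    r = r12 + r21 * theta * t

    # Stokes relations for the remaining N - 1 plates
    rt_sum = r + t
    D2 = (1.0 + rt_sum) * (1.0 + r - t) * (1.0 - r + t) * np.maximum(1.0 - rt_sum, 0.0)
    D = np.sqrt(D2)
    rq = r**2
    tq = t**2
    with np.errstate(divide="ignore", invalid="ignore"):
        a = (1.0 + rq - tq + D) / (2.0 * r)
        b = (1.0 - rq + tq + D) / (2.0 * t)
        bNm1 = b ** (leaf.N_struct - 1.0)
        bN2 = bNm1**2
        a2 = a**2
        denom_s = a2 * bN2 - 1.0
        Rsub = a * (bN2 - 1.0) / denom_s
        Tsub = bNm1 * (a2 - 1.0) / denom_s

    # non-absorbing limit where r + t -> 1
    flat = rt_sum >= 1.0 - 1e-12
    if np.any(flat):
        tf = t[flat]
        Tsub = np.asarray(Tsub)
        Rsub = np.asarray(Rsub)
        Tsub[flat] = tf / (tf + (1.0 - tf) * (leaf.N_struct - 1.0))
        Rsub[flat] = 1.0 - Tsub[flat]

    denom_f = 1.0 - Rsub * r
    refl = Ra + Ta * Rsub * t / denom_f
    trans = Ta * Tsub / denom_f

    refl = np.clip(refl, 0.0, 1.0)
    trans = np.clip(trans, 0.0, 1.0 - refl)
    return refl, trans
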