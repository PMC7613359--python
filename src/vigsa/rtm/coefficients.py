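"""Spectral coefficient tables and background soil spectra.

The leaf model needs, per 1-nm wavelength from 400 to 2500 nm, the leaf
refractive index and the specific absorption coefficients of chlorophyll
a+b, water and dry matter.  Real tables can be loaded from a plain-text file
(:func:`load_coefficients`); the bundled default
(:func:`synthetic_coefficients`) is a *synthetic* stand-in generated from
smooth analytic features whose positions and magnitudes follow the known
physics:

* chlorophyll a+b absorbs in the blue (~430 nm) and red (~670 nm) with
  specific absorption of order 0.1 cm^2/ug, and is transparent beyond the
  red edge;
* liquid water absorption (per cm of equivalent water thickness) follows the
  well-known pure-water magnitudes: weak overtones near 970 and 1200 nm,
  strong bands near 1450 and 1940 nm, and a rising continuum toward 2500 nm;
* dry matter absorbs weakly in the VNIR and increasingly in the SWIR with
  cellulose/lignin features near 1730, 2100 and 2300 nm.

The synthetic table preserves the qualitative spectral behaviour the
simulations rely on (which variable controls which spectral region) but is
not the measured calibration of any real leaf dataset.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "WAVELENGTHS_1NM",
    "WAVELENGTHS_5NM",
    "SpectralCoefficients",
    "synthetic_coefficients",
    "load_coefficients",
    "synthetic_soil_spectrum",
    "load_soil_spectrum",
]

#: Native simulation grid: 400..2500 nm at 1 nm (2101 samples).
WAVELENGTHS_1NM = np.arange(400.0, 2501.0, 1.0)
#: Coarse forest-model grid: 400..2500 nm at 5 nm (421 samples).
WAVELENGTHS_5NM = np.arange(400.0, 2501.0, 5.0)

REQUIRED_COLUMNS = ("wavelength_nm", "refractive_index", "k_Cab", "k_Cw", "k_Cm")


@dataclass(frozen=True)
class SpectralCoefficients:
    """Wavelength-indexed leaf optical coefficients on the 1-nm grid."""

    wavelengths: np.ndarray
    refractive_index: np.ndarray
    k_Cab: np.ndarray  # cm^2 / ug
    k_Cw: np.ndarray   # 1 / cm
    k_Cm: np.ndarray   # cm^2 / g
    source: str = "synthetic"

    def __post_init__(self) -> None:
        n = self.wavelengths.size
        if n != WAVELENGTHS_1NM.size or not np.allclose(
            self.wavelengths, WAVELENGTHS_1NM
        ):
            raise ValueError(
                "coefficient table must cover 400-2500 nm at 1 nm (2101 rows)"
            )
        for name in ("refractive_index", "k_Cab", "k_Cw", "k_Cm"):
            v = getattr(self, name)
            if v.shape != (n,) or not np.all(np.isfinite(v)):
                raise ValueError(f"column {name}: wrong shape or non-finite values")
        if np.any(self.refractive_index <= 1.0):
            raise ValueError("refractive index must exceed 1")
        if min(self.k_Cab.min(), self.k_Cw.min(), self.k_Cm.min()) < 0:
            raise ValueError("absorption coefficients must be nonnegative")


def _gauss(wl: np.ndarray, center: float, sigma: float, amp: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((wl - center) / sigma) ** 2)


def synthetic_coefficients() -> SpectralCoefficients:
    """Bundled synthetic coefficient table (see module docstring)."""
    wl = WAVELENGTHS_1NM

    n = 1.40 + 0.12 * np.exp(-(wl - 400.0) / 900.0)

    k_cab = (
        _gauss(wl, 430.0, 34.0, 0.110)
        + _gauss(wl, 600.0, 55.0, 0.022)
        + _gauss(wl, 668.0, 26.0, 0.072)
    )
    # chlorophyll is transparent beyond the red edge
    k_cab = k_cab * (1.0 / (1.0 + np.exp((wl - 745.0) / 8.0)))

    k_cw = (
        _gauss(wl, 970.0, 35.0, 0.48)
        + _gauss(wl, 1200.0, 45.0, 1.1)
        + _gauss(wl, 1450.0, 55.0, 29.0)
        + _gauss(wl, 1790.0, 60.0, 6.0)
        + _gauss(wl, 1940.0, 65.0, 120.0)
        + _gauss(wl, 2270.0, 90.0, 40.0)
        + 60.0 / (1.0 + np.exp(-(wl - 2450.0) / 90.0))
    )

    k_cm = (
        0.6
        + 14.0 / (1.0 + np.exp(-(wl - 1550.0) / 280.0))
        + _gauss(wl, 1730.0, 45.0, 8.0)
        + _gauss(wl, 2100.0, 60.0, 22.0)
        + _gauss(wl, 2300.0, 70.0, 28.0)
    )

    return SpectralCoefficients(
        wavelengths=wl,
        refractive_index=n,
        k_Cab=k_cab,
        k_Cw=k_cw,
        k_Cm=k_cm,
        source="synthetic",
    )


def load_coefficients(path, sha256: str | None = None) -> SpectralCoefficients:
    """Load a coefficient table from a whitespace- or comma-separated file.

    The file must contain the columns ``wavelength_nm, refractive_index,
    k_Cab, k_Cw, k_Cm`` covering 400-2500 nm at 1 nm.  If ``sha256`` is
    given, the file's digest is verified before parsing.
    """
    if sha256 is not None:
        digest = hashlib.sha256(open(path, "rb").read()).hexdigest()
        if digest != sha256:
            raise ValueError(
                f"coefficient file checksum mismatch: {digest} != {sha256}"
            )
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"coefficient file missing columns: {missing}")
    df = df.sort_values("wavelength_nm")
    return SpectralCoefficients(
        wavelengths=df["wavelength_nm"].to_numpy(dtype=float),
        refractive_index=df["refractive_index"].to_numpy(dtype=float),
        k_Cab=df["k_Cab"].to_numpy(dtype=float),
        k_Cw=df["k_Cw"].to_numpy(dtype=float),
        k_Cm=df["k_Cm"].to_numpy(dtype=float),
        source=str(path),
    )


def write_coefficients(coeffs: SpectralCoefficients, path) -> None:
    """Write a coefficient table in the plain-text interchange format."""
    pd.DataFrame(
        {
            "wavelength_nm": coeffs.wavelengths,
            "refractive_index": coeffs.refractive_index,
            "k_Cab": coeffs.k_Cab,
            "k_Cw": coeffs.k_Cw,
            "k_Cm": coeffs.k_Cm,
        }
    ).to_csv(path, index=False)


def synthetic_soil_spectrum(wavelengths: np.ndarray | None = None) -> np.ndarray:
    """Synthetic dry-soil reflectance on the given grid (default 1 nm).

    A smooth brightness curve rising from the blue into the SWIR with
    moisture/clay absorption dips near 1450, 1930 and 2210 nm, typical of a
    bright dry soil.  Multiplied by the scalar soil brightness coefficient
    (0..1) it spans dark (wet) to bright (dry) backgrounds.
    """
    wl = WAVELENGTHS_1NM if wavelengths is None else np.asarray(wavelengths, float)
    r = 0.05 + 0.33 * (1.0 - np.exp(-(wl - 390.0) / 900.0))
    r -= _gauss(wl, 1450.0, 70.0, 0.035)
    r -= _gauss(wl, 1930.0, 85.0, 0.060)
    r -= _gauss(wl, 2210.0, 60.0, 0.030)
    return np.clip(r, 0.0, 1.0)


def load_soil_spectrum(path, wavelengths: np.ndarray | None = None) -> np.ndarray:
    """Load a two-column wavelength/reflectance table, interpolated onto
    ``wavelengths`` (default: the 1-nm grid)."""
    wl = WAVELENGTHS_1NM if wavelengths is None else np.asarray(wavelengths, float)
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    if df.shape[1] < 2:
        raise ValueError("soil file needs two columns: wavelength, reflectance")
    x = df.iloc[:, 0].to_numpy(dtype=float)
    y = df.iloc[:, 1].to_numpy(dtype=float)
    order = np.argsort(x)
    r = np.interp(wl, x[order], y[order])
    if np.any((r < 0) | (r > 1)):
        raise ValueError("soil reflectance must lie in [0, 1]")
    return r
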