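"""INFORM-style hybrid forest reflectance model.

The forest scene couples a turbid-medium description of tree crowns and
understory (both run through the four-stream canopy model) with a
geometric-optical scene mixture in the spirit of FLIM: the observed
reflectance is composed of crown-covered area, sunlit open understory and
shadowed open understory, with semi-transparent crowns.

Per simulation the model runs the turbid-medium solver twice on the 5-nm
grid:

1. understory layer (LAI of the understory over the soil, with a fixed
   spherical leaf-angle distribution) -> ``rho_u``;
2. crown layer at the single-tree LAI over the understory background, with
   the sampled mean leaf angle -> ``rho_c``; its directional extinction
   coefficients give the crown transmittances in the sun and view
   directions, ``Ts = exp(-ks LAIs)``, ``To = exp(-ko LAIs)``.

Crown cover seen at nadir follows Poisson crown overlap,
``1 - exp(-SD * pi CD^2 / 4 / 1e4)``, which stays in [0, 1] and saturates
smoothly; the crown-shadow fraction uses the same form with the projected
area scaled by 1/cos(SZA).  A shadow is only visible
where it escapes from under its casting crown, which happens once the
horizontal shadow offset ``H tan(SZA)`` is large against the crown diameter
— this is the (weak) channel through which tree height enters.  The scene
mixture is then

    R = co * rho_c + (1 - co) * [(1 - cs) rho_u + cs rho_u Ts]
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coefficients import WAVELENGTHS_1NM, WAVELENGTHS_5NM
from .sail import campbell_lidf, foursail

__all__ = ["CanopyParamsINFORM", "inform_toc", "to_5nm_grid"]

#: Fixed mean leaf inclination (degrees) of the understory layer; the
#: sampled LAD input describes the tree crowns only.
UNDERSTORY_MEAN_LEAF_ANGLE = 57.0


@dataclass(frozen=True)
class CanopyParamsINFORM:
    """Forest canopy inputs.

    LAIs : single-tree leaf area index (within a crown footprint), m^2/m^2
    LAIu : understory leaf area index, m^2/m^2
    SD : stem density, trees/ha
    H : tree height, m
    CD : crown diameter, m
    LAD, soil_coeff, SZA, OZA, RAA, hotspot, skyl : as in the homogeneous model
    """

    LAIs: float
    LAIu: float
    SD: float
    H: float
    CD: float
    LAD: float = 57.0
    soil_coeff: float = 0.5
    SZA: float = 30.0
    OZA: float = 0.0
    RAA: float = 0.0
    hotspot: float = 0.01
    skyl: float = 0.0

    def __post_init__(self) -> None:
        if min(self.LAIs, self.LAIu) < 0:
            raise ValueError("leaf area indices must be nonnegative")
        if self.SD <= 0 or self.H <= 0 or self.CD <= 0:
            raise ValueError("SD, H and CD must be positive")
        if not 0.0 <= self.LAD <= 90.0:
            raise ValueError("LAD must lie in [0, 90] degrees")
        if not 0.0 <= self.SZA < 90.0 or not 0.0 <= self.OZA < 90.0:
            raise ValueError("zenith angles must lie in [0, 90) degrees")
        if not 0.0 <= self.soil_coeff <= 1.0:
            raise ValueError("soil_coeff must lie in [0, 1]")


def to_5nm_grid(spectrum_1nm: np.ndarray) -> np.ndarray:
    """Block-average a 1-nm 400-2500 spectrum onto the 421-band 5-nm grid.

    Each 5-nm band value is the mean of the 1-nm samples within +/- 2 nm of
    the band center."""
    s = np.asarray(spectrum_1nm, dtype=float)
    n = WAVELENGTHS_1NM.size
    if s.shape[-1] != n:
        raise ValueError("expected a 2101-sample 1-nm spectrum")
    centers = (WAVELENGTHS_5NM - 400.0).astype(int)
    lo = np.clip(centers - 2, 0, n)
    hi = np.clip(centers + 3, 0, n)
    cs = np.concatenate(
        [np.zeros(s.shape[:-1] + (1,)), np.cumsum(s, axis=-1)], axis=-1
    )
    return (cs[..., hi] - cs[..., lo]) / (hi - lo)


def inform_toc(
    leaf_rt: tuple[np.ndarray, np.ndarray],
    forest: CanopyParamsINFORM,
    soil_spectrum: np.ndarray,
) -> np.ndarray:
    """Top-of-canopy bidirectional forest reflectance on the 5-nm grid.

    ``leaf_rt`` and ``soil_spectrum`` may be given on the 1-nm grid (they are
    block-averaged down) or directly on the 5-nm grid.
    """
    rho, tau = leaf_rt
    if rho.shape[-1] == WAVELENGTHS_1NM.size:
        rho, tau = to_5nm_grid(rho), to_5nm_grid(tau)
        soil_spectrum = to_5nm_grid(np.asarray(soil_spectrum, dtype=float))
    soil_spectrum = np.asarray(soil_spectrum, dtype=float)
    if rho.shape != soil_spectrum.shape:
        raise ValueError("leaf and soil spectra are on different grids")

    # the mean leaf angle characterizes the tree crowns; the understory
    # layer keeps a default (spherical) leaf angle distribution
    lidf_crown = campbell_lidf(forest.LAD)
    lidf_under = campbell_lidf(UNDERSTORY_MEAN_LEAF_ANGLE)
    rsoil = forest.soil_coeff * soil_spectrum
    geom = dict(
        hotspot=forest.hotspot, tts=forest.SZA, tto=forest.OZA, psi=forest.RAA
    )

    # understory over soil
    if forest.LAIu > 0.0:
        under = foursail(rho, tau, lidf_under, lai=forest.LAIu, rsoil=rsoil, **geom)
        rho_u = under.toc(forest.skyl)
    else:
        rho_u = rsoil.copy()

    # turbid-medium crown layer at the single-tree LAI over the understory
    crown = foursail(rho, tau, lidf_crown, lai=forest.LAIs, rsoil=rho_u, **geom)
    rho_c = crown.toc(forest.skyl)

    # crown transparency in the sun and view directions
    Ts = np.exp(-crown.ks * forest.LAIs)
    To = np.exp(-crown.ko * forest.LAIs)

    # geometric scene fractions; Poisson crown overlap keeps cover in [0, 1]
    # and saturating smoothly, so crown geometry stays influential in dense
    # stands instead of being clipped out
    crown_area = np.pi * forest.CD**2 / 4.0  # m^2 per tree
    density = forest.SD / 10_000.0           # trees per m^2
    co = 1.0 - np.exp(-density * crown_area)            # crown cover at nadir
    cts = np.cos(np.radians(forest.SZA))
    cs = 1.0 - np.exp(-density * crown_area / cts)      # crown shadow cover
    # shadow visibility: offset of the shadow from its casting crown
    offset = forest.H * np.tan(np.radians(forest.SZA))
    cs_visible = cs * (1.0 - np.exp(-offset / forest.CD))

    r = (
        co * rho_c
        + (1.0 - co) * ((1.0 - cs_visible) * rho_u + cs_visible * rho_u * Ts)
    )
    return np.clip(r, 0.0, 1.0)
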