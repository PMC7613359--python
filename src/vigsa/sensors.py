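"""Sensor band settings and spectral convolution.

Each sensor is an ordered list of bands with center wavelength and FWHM;
simulated spectra are convolved to band reflectances through a spectral
response function (SRF) built from center/FWHM (Gaussian by default, boxcar
optional) or supplied as a tabulated response.  A role map assigns the
physical band that plays BLUE/GREEN/RED/RedEdge/NIR/SWIR in broadband index
formulas; the bundled maps are conventional choices and user-overridable.

Bundled definitions cover Landsat 8 OLI, MODIS (reflective bands), the
Sentinel-2 MSI, Sentinel-3 (OLCI and SLSTR treated as one logical sensor)
and the EnMAP imaging spectrometer.  Only bands within the simulated
400-2500 nm range are modeled.  The EnMAP grid is a nominal synthetic
layout: 89 VNIR bands at 6.5 nm and 141 SWIR bands at 10 nm sampling (230
bands), placed so that the conventional role wavelengths (449.25, 527.25,
670.25, 709.25, 1085 and 2195 nm) fall exactly on band centers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SensorBand",
    "Sensor",
    "BandView",
    "band_srf",
    "convolve_to_sensor",
    "nearest_band_value",
    "get_sensor",
    "list_sensors",
    "load_sensor",
    "ROLES",
    "DEFAULT_ROLE_WAVELENGTHS",
]

ROLES = ("BLUE", "GREEN", "RED", "RedEdge", "NIR", "SWIR")

#: Nominal role wavelengths used when evaluating role-based indices directly
#: on a native simulation grid (no sensor selected).
DEFAULT_ROLE_WAVELENGTHS = {
    "BLUE": 490.0,
    "GREEN": 560.0,
    "RED": 665.0,
    "RedEdge": 705.0,
    "NIR": 865.0,
    "SWIR": 1610.0,
}

#: Maximum |target - band center| accepted when resolving an explicit
#: wavelength on a discrete sensor band set.
MAX_BAND_DISTANCE_NM = 100.0


@dataclass(frozen=True)
class SensorBand:
    band_name: str
    center: float  # nm
    fwhm: float    # nm
    srf: np.ndarray | None = None  # optional tabulated response on the sim grid

    def __post_init__(self) -> None:
        if not 400.0 <= self.center <= 2500.0:
            raise ValueError(
                f"band {self.band_name}: center {self.center} nm outside 400-2500"
            )
        if self.fwhm <= 0:
            raise ValueError(f"band {self.band_name}: fwhm must be positive")
        if self.srf is not None and np.any(self.srf < 0):
            raise ValueError(f"band {self.band_name}: tabulated SRF must be >= 0")


@dataclass(frozen=True)
class Sensor:
    name: str
    bands: tuple[SensorBand, ...]
    roles: dict = field(default_factory=dict)  # role -> band_name

    def __post_init__(self) -> None:
        names = [b.band_name for b in self.bands]
        if len(set(names)) != len(names):
            raise ValueError(f"{self.name}: band names must be unique")
        for role, bname in self.roles.items():
            if role not in ROLES:
                raise ValueError(f"{self.name}: unknown role {role}")
            if bname not in names:
                raise ValueError(f"{self.name}: role {role} -> unknown band {bname}")

    @property
    def centers(self) -> np.ndarray:
        return np.array([b.center for b in self.bands])

    def band(self, band_name: str) -> SensorBand:
        for b in self.bands:
            if b.band_name == band_name:
                return b
        raise KeyError(band_name)


def band_srf(
    center: float, fwhm: float, shape: str, grid: np.ndarray
) -> np.ndarray:
    """Normalized SRF weights of one band on a wavelength grid.

    ``gaussian`` weights fall to half their peak at center +/- fwhm/2 before
    normalization; ``boxcar`` covers [center - fwhm/2, center + fwhm/2]."""
    grid = np.asarray(grid, dtype=float)
    if not 400.0 <= center <= 2500.0:
        raise ValueError(f"band center {center} nm outside the 400-2500 nm range")
    if shape == "gaussian":
        sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        w = np.exp(-0.5 * ((grid - center) / sigma) ** 2)
        # negligible tails beyond 3 FWHM keep bands compactly supported
        w[np.abs(grid - center) > 3.0 * fwhm] = 0.0
    elif shape == "boxcar":
        w = (np.abs(grid - center) <= fwhm / 2.0).astype(float)
    else:
        raise ValueError(f"unknown SRF shape {shape!r}")
    total = w.sum()
    if total <= 0.0:
        raise ValueError(
            f"band at {center} nm (fwhm {fwhm}) has no support on the grid"
        )
    return w / total


@dataclass
class BandView:
    """Band reflectances of a simulation set: (n_sim, n_band) matrix with
    band metadata and role resolution."""

    sensor: Sensor
    values: np.ndarray
    band_names: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.band_names)

    def role(self, role: str) -> np.ndarray:
        if role not in self.sensor.roles:
            raise KeyError(
                f"sensor {self.sensor.name} has no band assigned to role {role}"
            )
        return self.values[:, self.band_names.index(self.sensor.roles[role])]

    def rho(self, wavelength: float, max_distance: float = MAX_BAND_DISTANCE_NM):
        centers = np.array(
            [self.sensor.band(n).center for n in self.band_names]
        )
        d = np.abs(centers - wavelength)
        j = int(np.argmin(d))
        # ties toward the lower wavelength
        tied = np.flatnonzero(np.isclose(d, d[j]))
        j = int(tied[np.argmin(centers[tied])])
        if d[j] > max_distance:
            raise ValueError(
                f"no {self.sensor.name} band within {max_distance} nm of "
                f"{wavelength} nm (nearest: {centers[j]} nm)"
            )
        return self.values[:, j]


def convolve_to_sensor(
    wavelengths: np.ndarray,
    values: np.ndarray,
    sensor: Sensor,
    shape: str = "gaussian",
) -> BandView:
    """Convolve spectra (n_sim, n_wl) to sensor band reflectances.

    Bands whose SRF has no support on the grid raise.  Tabulated SRFs on a
    band override the analytic shape."""
    wavelengths = np.asarray(wavelengths, dtype=float)
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[1] != wavelengths.size:
        raise ValueError("spectra and wavelength grid have different lengths")
    W = np.empty((wavelengths.size, len(sensor.bands)))
    for j, b in enumerate(sensor.bands):
        if b.srf is not None:
            w = np.asarray(b.srf, dtype=float)
            if w.size != wavelengths.size or w.sum() <= 0:
                raise ValueError(f"band {b.band_name}: bad tabulated SRF")
            W[:, j] = w / w.sum()
        else:
            W[:, j] = band_srf(b.center, b.fwhm, shape, wavelengths)
    return BandView(
        sensor=sensor,
        values=values @ W,
        band_names=[b.band_name for b in sensor.bands],
    )


def nearest_band_value(
    wavelengths: np.ndarray, values: np.ndarray, wavelength: float
) -> np.ndarray:
    """Spectrum value at the grid point nearest to ``wavelength`` (ties
    toward the lower wavelength)."""
    wavelengths = np.asarray(wavelengths, dtype=float)
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if not wavelengths.min() <= wavelength <= wavelengths.max():
        raise ValueError(
            f"{wavelength} nm outside grid coverage "
            f"[{wavelengths.min()}, {wavelengths.max()}]"
        )
    d = np.abs(wavelengths - wavelength)
    j = int(np.argmin(d))
    if j > 0 and np.isclose(d[j - 1], d[j]):
        j -= 1
    return values[:, j]


# ---------------------------------------------------------------------------
# bundled sensor definitions
# ---------------------------------------------------------------------------

def _bands(rows) -> tuple[SensorBand, ...]:
    return tuple(SensorBand(n, c, f) for n, c, f in rows)


def _enmap_bands() -> tuple[SensorBand, ...]:
    vnir = [("E_V%02d" % m, 423.25 + 6.5 * m, 8.0) for m in range(89)]
    swir = [("E_S%03d" % m, 1005.0 + 10.0 * m, 12.0) for m in range(141)]
    return _bands(vnir + swir)


_BUILTIN: dict[str, Sensor] = {}


def _register(name: str, bands, roles) -> None:
    _BUILTIN[name] = Sensor(name=name, bands=bands, roles=roles)


_register(
    "Landsat8",
    _bands([
        ("B1", 443.0, 16.0), ("B2", 482.0, 60.0), ("B3", 561.4, 57.0),
        ("B4", 654.6, 37.0), ("B5", 865.0, 28.0), ("B6", 1608.9, 85.0),
        ("B7", 2200.7, 187.0), ("B9", 1373.0, 20.0),
    ]),
    {"BLUE": "B2", "GREEN": "B3", "RED": "B4", "NIR": "B5", "SWIR": "B6"},
)

_register(
    "MODIS",
    _bands([
        ("B1", 645.0, 50.0), ("B2", 858.5, 35.0), ("B3", 469.0, 20.0),
        ("B4", 555.0, 20.0), ("B5", 1240.0, 20.0), ("B6", 1640.0, 24.0),
        ("B7", 2130.0, 50.0), ("B8", 412.5, 15.0), ("B9", 443.0, 10.0),
        ("B10", 488.0, 10.0), ("B11", 531.0, 10.0), ("B12", 551.0, 10.0),
        ("B13", 667.0, 10.0), ("B14", 678.0, 10.0), ("B15", 748.0, 10.0),
        ("B16", 869.5, 15.0), ("B17", 905.0, 30.0), ("B18", 936.0, 10.0),
        ("B19", 940.0, 50.0), ("B26", 1375.0, 30.0),
    ]),
    {"BLUE": "B3", "GREEN": "B4", "RED": "B1", "NIR": "B2", "SWIR": "B6"},
)

_register(
    "Sentinel2",
    _bands([
        ("B1", 442.7, 21.0), ("B2", 492.4, 66.0), ("B3", 559.8, 36.0),
        ("B4", 664.6, 31.0), ("B5", 704.1, 15.0), ("B6", 740.5, 15.0),
        ("B7", 782.8, 20.0), ("B8", 832.8, 106.0), ("B8a", 864.7, 21.0),
        ("B9", 945.0, 20.0), ("B10", 1373.5, 31.0), ("B11", 1613.7, 91.0),
        ("B12", 2202.4, 175.0),
    ]),
    {"BLUE": "B2", "GREEN": "B3", "RED": "B4", "RedEdge": "B5",
     "NIR": "B8", "SWIR": "B11"},
)

# one logical sensor: OLCI covers the VNIR roles, SLSTR contributes the SWIR
_register(
    "Sentinel3",
    _bands([
        ("Oa01", 400.0, 15.0), ("Oa02", 412.5, 10.0), ("Oa03", 442.5, 10.0),
        ("Oa04", 490.0, 10.0), ("Oa05", 510.0, 10.0), ("Oa06", 560.0, 10.0),
        ("Oa07", 620.0, 10.0), ("Oa08", 665.0, 10.0), ("Oa09", 673.75, 7.5),
        ("Oa10", 681.25, 7.5), ("Oa11", 708.75, 10.0), ("Oa12", 753.75, 7.5),
        ("Oa13", 761.25, 2.5), ("Oa14", 764.375, 3.75), ("Oa15", 767.5, 2.5),
        ("Oa16", 778.75, 15.0), ("Oa17", 865.0, 20.0), ("Oa18", 885.0, 10.0),
        ("Oa19", 900.0, 10.0), ("Oa20", 940.0, 20.0), ("Oa21", 1020.0, 40.0),
        ("S1", 554.27, 19.26), ("S2", 659.47, 19.25), ("S3", 868.0, 20.6),
        ("S4", 1374.8, 20.8), ("S5", 1613.4, 60.68), ("S6", 2255.7, 50.15),
    ]),
    {"BLUE": "Oa04", "GREEN": "Oa06", "RED": "Oa08", "RedEdge": "Oa11",
     "NIR": "Oa17", "SWIR": "S5"},
)

_register(
    "EnMAP",
    _enmap_bands(),
    {"BLUE": "E_V04", "GREEN": "E_V16", "RED": "E_V38", "RedEdge": "E_V44",
     "NIR": "E_S008", "SWIR": "E_S119"},
)

assert len(_BUILTIN["EnMAP"].bands) == 230


def get_sensor(name: str) -> Sensor:
    """Bundled sensor by name (Landsat8, MODIS, Sentinel2, Sentinel3, EnMAP)."""
    try:
        return _BUILTIN[name]
    except KeyError:
        raise KeyError(
            f"unknown sensor {name!r}; available: {sorted(_BUILTIN)}"
        ) from None


def list_sensors() -> list[str]:
    return sorted(_BUILTIN)


def load_sensor(path, name: str | None = None, roles: dict | None = None) -> Sensor:
    """Load a sensor definition from a CSV (band_name, center_nm, fwhm_nm)
    or JSON file ({"name", "roles", "bands": [...]})."""
    path = str(path)
    if path.endswith(".json"):
        cfg = json.load(open(path))
        bands = _bands(
            [(b["band_name"], b["center_nm"], b["fwhm_nm"]) for b in cfg["bands"]]
        )
        return Sensor(
            name=name or cfg.get("name", "custom"),
            bands=bands,
            roles=roles or cfg.get("roles", {}),
        )
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    bands = _bands(
        list(zip(df["band_name"], df["center_nm"].astype(float),
                 df["fwhm_nm"].astype(float)))
    )
    return Sensor(name=name or "custom", bands=bands, roles=roles or {})
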