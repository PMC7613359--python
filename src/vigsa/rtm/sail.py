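"""4SAIL turbid-medium canopy reflectance model.

The canopy is a horizontally homogeneous layer of small absorbing/scattering
leaf elements above a Lambertian soil.  The four-stream approximation tracks
the direct solar flux, the flux in the viewing direction and the two diffuse
hemispherical fluxes; leaf inclination enters through a discretized leaf
inclination distribution derived from the mean leaf angle via Campbell's
ellipsoidal parameterization, and the hot-spot correction follows the
standard exponential gap-correlation integral.

Geometry convention: solar zenith ``tts``, observer zenith ``tto`` and
relative azimuth ``psi`` in degrees; the bidirectional top-of-canopy
reflectance factor is returned for direct solar illumination, optionally
mixed with the hemispherical-directional term for a diffuse irradiance
fraction ``skyl``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CanopyParamsSAIL", "campbell_lidf", "sail_toc", "foursail", "SailFluxes"]

#: Leaf inclination class centers (degrees): 10-degree steps to 80, then 2-degree.
LITAB = np.array([5, 15, 25, 35, 45, 55, 65, 75, 81, 83, 85, 87, 89], dtype=float)
_TL1 = np.array([0, 10, 20, 30, 40, 50, 60, 70, 80, 82, 84, 86, 88], dtype=float)
_TL2 = np.array([10, 20, 30, 40, 50, 60, 70, 80, 82, 84, 86, 88, 90], dtype=float)


@dataclass(frozen=True)
class CanopyParamsSAIL:
    """SAIL canopy inputs for a homogeneous (crop-like) canopy.

    LAI : total one-sided leaf area index, m^2/m^2
    LAD : mean leaf inclination angle, degrees (0 horizontal .. 90 vertical)
    soil_coeff : soil brightness coefficient in [0, 1], multiplies the
        reference dry-soil spectrum
    SZA, OZA, RAA : solar zenith, observer zenith, relative azimuth (deg)
    hotspot : hot-spot parameter (leaf size / canopy height ratio)
    skyl : fraction of diffuse sky irradiance
    """

    LAI: float
    LAD: float = 57.0
    soil_coeff: float = 0.5
    SZA: float = 30.0
    OZA: float = 0.0
    RAA: float = 0.0
    hotspot: float = 0.01
    skyl: float = 0.0

    def __post_init__(self) -> None:
        if self.LAI < 0:
            raise ValueError("LAI must be nonnegative")
        if not 0.0 <= self.LAD <= 90.0:
            raise ValueError("LAD (mean leaf angle) must lie in [0, 90] degrees")
        if not 0.0 <= self.SZA < 90.0 or not 0.0 <= self.OZA < 90.0:
            raise ValueError("zenith angles must lie in [0, 90) degrees")
        if not 0.0 <= self.soil_coeff <= 1.0:
            raise ValueError("soil_coeff must lie in [0, 1]")


def campbell_lidf(mean_angle_deg: float) -> np.ndarray:
    """Leaf-inclination class frequencies for an ellipsoidal distribution
    with the given mean leaf angle, on the 13 classes of :data:`LITAB`."""
    ala = float(np.clip(mean_angle_deg, 0.5, 89.5))
    excent = np.exp(
        -1.6184e-5 * ala**3 + 2.1145e-3 * ala**2 - 1.2390e-1 * ala + 3.2491
    )
    freq = np.empty_like(LITAB)
    for i, (tl1, tl2) in enumerate(zip(_TL1, _TL2)):
        x1 = excent / np.sqrt(1.0 + excent**2 * np.tan(np.radians(tl1)) ** 2)
        x2 = excent / np.sqrt(1.0 + excent**2 * np.tan(np.radians(tl2)) ** 2)
        if abs(excent - 1.0) < 1e-9:
            freq[i] = abs(np.cos(np.radians(tl1)) - np.cos(np.radians(tl2)))
        else:
            alpha = excent / np.sqrt(abs(1.0 - excent**2))
            alpha2 = alpha**2
            x12, x22 = x1**2, x2**2
            if excent > 1.0:
                alpx1 = np.sqrt(alpha2 + x12)
                alpx2 = np.sqrt(alpha2 + x22)
                dum1 = x1 * alpx1 + alpha2 * np.log(x1 + alpx1)
                dum2 = x2 * alpx2 + alpha2 * np.log(x2 + alpx2)
            else:
                almx1 = np.sqrt(alpha2 - x12)
                almx2 = np.sqrt(alpha2 - x22)
                dum1 = x1 * almx1 + alpha2 * np.arcsin(x1 / alpha)
                dum2 = x2 * almx2 + alpha2 * np.arcsin(x2 / alpha)
            freq[i] = abs(dum1 - dum2)
    return freq / freq.sum()


def _volscatt(tts: float, tto: float, psi: float, ttl: float):
    """Geometric factors of one leaf-inclination class: fractions of doubly
    illuminated/viewed leaf area (chi_s, chi_o) and the bidirectional
    scattering integrals (frho, ftau)."""
    cts, cto = np.cos(np.radians(tts)), np.cos(np.radians(tto))
    sts, sto = np.sin(np.radians(tts)), np.sin(np.radians(tto))
    cospsi = np.cos(np.radians(psi))
    psir = np.radians(psi)
    cttl, sttl = np.cos(np.radians(ttl)), np.sin(np.radians(ttl))

    cs = cttl * cts
    co = cttl * cto
    ss = sttl * sts
    so = sttl * sto

    cosbts = -cs / ss if abs(ss) > 1e-6 else 5.0
    cosbto = -co / so if abs(so) > 1e-6 else 5.0

    if abs(cosbts) < 1.0:
        bts = np.arccos(cosbts)
        ds = ss
    else:
        bts = np.pi
        ds = cs
    chi_s = 2.0 / np.pi * ((bts - np.pi / 2.0) * cs + np.sin(bts) * ss)

    if abs(cosbto) < 1.0:
        bto = np.arccos(cosbto)
        do_ = so
    else:
        bto = np.pi if tto < 90.0 else 0.0
        do_ = co if tto < 90.0 else -co
    chi_o = 2.0 / np.pi * ((bto - np.pi / 2.0) * co + np.sin(bto) * so)

    btran1 = abs(bts - bto)
    btran2 = np.pi - abs(bts + bto - np.pi)
    if psir <= btran1:
        bt1, bt2, bt3 = psir, btran1, btran2
    elif psir <= btran2:
        bt1, bt2, bt3 = btran1, psir, btran2
    else:
        bt1, bt2, bt3 = btran1, btran2, psir

    t1 = 2.0 * cs * co + ss * so * cospsi
    t2 = 0.0
    if bt2 > 0.0:
        t2 = np.sin(bt2) * (2.0 * ds * do_ + ss * so * np.cos(bt1) * np.cos(bt3))
    denom = 2.0 * np.pi**2
    frho = max(((np.pi - bt2) * t1 + t2) / denom, 0.0)
    ftau = max((-bt2 * t1 + t2) / denom, 0.0)
    return chi_s, chi_o, frho, ftau


def _jfunc1(k: float, m: np.ndarray, lai: float) -> np.ndarray:
    d = (k - m) * lai
    out = np.empty_like(m)
    big = np.abs(d) > 1e-3
    out[big] = (np.exp(-m[big] * lai) - np.exp(-k * lai)) / (k - m[big])
    small = ~big
    out[small] = (
        0.5 * lai * (np.exp(-k * lai) + np.exp(-m[small] * lai))
        * (1.0 - d[small] ** 2 / 12.0)
    )
    return out


def _jfunc2(k: float, m: np.ndarray, lai: float) -> np.ndarray:
    return (1.0 - np.exp(-(k + m) * lai)) / (k + m)


@dataclass
class SailFluxes:
    """Per-wavelength surface reflectance factors plus the direction-only
    extinction coefficients (for coupling into the forest model)."""

    rsot: np.ndarray   # bidirectional
    rdot: np.ndarray   # hemispherical-directional
    rsdt: np.ndarray   # directional-hemispherical
    rddt: np.ndarray   # bihemispherical
    ks: float          # extinction in the solar direction (per unit LAI)
    ko: float          # extinction in the viewing direction

    def toc(self, skyl: float = 0.0) -> np.ndarray:
        """Observed reflectance for a diffuse irradiance fraction ``skyl``."""
        return (1.0 - skyl) * self.rsot + skyl * self.rdot


def foursail(
    rho: np.ndarray,
    tau: np.ndarray,
    lidf: np.ndarray,
    lai: float,
    hotspot: float,
    tts: float,
    tto: float,
    psi: float,
    rsoil: np.ndarray,
) -> SailFluxes:
    """Run the four-stream canopy model for one set of structural inputs.

    ``rho``/``tau`` are leaf reflectance/transmittance spectra, ``rsoil`` the
    soil background spectrum on the same grid; ``lidf`` the 13-class leaf
    inclination frequencies.  Returns the four surface reflectance factors.
    """
    rho = np.asarray(rho, dtype=float)
    tau = np.asarray(tau, dtype=float)
    rsoil = np.asarray(rsoil, dtype=float)

    cts = np.cos(np.radians(tts))
    cto = np.cos(np.radians(tto))

    ks = ko = bf = sob = sof = 0.0
    for f, ttl in zip(lidf, LITAB):
        chi_s, chi_o, frho, ftau = _volscatt(tts, tto, psi, ttl)
        ks += chi_s / cts * f
        ko += chi_o / cto * f
        bf += np.cos(np.radians(ttl)) ** 2 * f
        sob += frho * np.pi / (cts * cto) * f
        sof += ftau * np.pi / (cts * cto) * f

    if lai <= 0.0:
        return SailFluxes(
            rsot=rsoil.copy(), rdot=rsoil.copy(),
            rsdt=rsoil.copy(), rddt=rsoil.copy(),
            ks=ks, ko=ko,
        )

    sdb, sdf = 0.5 * (ks + bf), 0.5 * (ks - bf)
    dob, dof = 0.5 * (ko + bf), 0.5 * (ko - bf)
    ddb, ddf = 0.5 * (1.0 + bf), 0.5 * (1.0 - bf)

    sigb = ddb * rho + ddf * tau
    sigf = ddf * rho + ddb * tau
    att = 1.0 - sigf
    m2 = np.maximum((att + sigb) * (att - sigb), 0.0)
    m = np.sqrt(m2)
    sb = sdb * rho + sdf * tau
    sf = sdf * rho + sdb * tau
    vb = dob * rho + dof * tau
    vf = dof * rho + dob * tau
    w = sob * rho + sof * tau

    e1 = np.exp(-m * lai)
    e2 = e1**2
    sigb_safe = np.where(sigb > 0.0, sigb, 1e-36)
    rinf = np.clip((att - m) / sigb_safe, -1.0, 1.0)
    rinf2 = rinf**2
    re = rinf * e1
    denom = np.maximum(1.0 - rinf2 * e2, 1e-12)

    J1ks = _jfunc1(ks, m, lai)
    J2ks = _jfunc2(ks, m, lai)
    J1ko = _jfunc1(ko, m, lai)
    J2ko = _jfunc2(ko, m, lai)

    Ps = (sf + sb * rinf) * J1ks
    Qs = (sf * rinf + sb) * J2ks
    Pv = (vf + vb * rinf) * J1ko
    Qv = (vf * rinf + vb) * J2ko

    rdd = rinf * (1.0 - e2) / denom
    tdd = (1.0 - rinf2) * e1 / denom
    tsd = (Ps - re * Qs) / denom
    rsd = (Qs - re * Ps) / denom
    tdo = (Pv - re * Qv) / denom
    rdo = (Qv - re * Pv) / denom

    tss = np.exp(-ks * lai)
    too = np.exp(-ko * lai)
    z = _jfunc2(ks, np.full(1, ko), lai)[0]
    g1 = (z - J1ko * tss) / (ks + m)
    g2 = (z - J1ks * too) / (ko + m)
    Tv1 = (vf * rinf + vb) * g1
    Tv2 = (vf + vb * rinf) * g2
    T1 = Tv1 * (sf + sb * rinf)
    T2 = Tv2 * (sf * rinf + sb)
    T3 = (rdo * Qs + tdo * Ps) * rinf
    rsod = (T1 + T2) * (1.0 - rinf2) / denom + T3

    # hot-spot single-scattering integral
    dso = np.sqrt(
        np.tan(np.radians(tts)) ** 2
        + np.tan(np.radians(tto)) ** 2
        - 2.0 * np.tan(np.radians(tts)) * np.tan(np.radians(tto))
        * np.cos(np.radians(psi))
    )
    alf = 1e36
    if hotspot > 0.0:
        alf = min((dso / hotspot) * 2.0 / (ks + ko), 200.0)
    if alf < 1e-12:
        tsstoo = tss
        sumint = (1.0 - tss) / (ks * lai)
    else:
        fhot = lai * np.sqrt(ko * ks)
        x1 = y1 = 0.0
        f1 = 1.0
        fint = (1.0 - np.exp(-alf)) * 0.05
        sumint = 0.0
        for istep in range(1, 21):
            x2 = 1.0 if istep == 20 else -np.log(1.0 - istep * fint) / alf
            y2 = -(ko + ks) * lai * x2 + fhot * (1.0 - np.exp(-alf * x2)) / alf
            f2 = np.exp(y2)
            if abs(y2 - y1) > 1e-30:
                sumint += (f2 - f1) * (x2 - x1) / (y2 - y1)
            x1, y1, f1 = x2, y2, f2
        tsstoo = f1
    rsos = w * lai * sumint

    # interaction with the Lambertian soil background
    dn = np.maximum(1.0 - rsoil * rdd, 1e-12)
    rddt = rdd + tdd * rsoil * tdd / dn
    rsdt = rsd + (tsd + tss) * rsoil * tdd / dn
    rdot = rdo + tdd * rsoil * (tdo + too) / dn
    rsodt = rsod + ((tss + tsd) * tdo + (tsd + tss * rsoil * rdd) * too) * rsoil / dn
    rsot = rsos + tsstoo * rsoil + rsodt

    return SailFluxes(
        rsot=np.clip(rsot, 0.0, 1.0),
        rdot=np.clip(rdot, 0.0, 1.0),
        rsdt=np.clip(rsdt, 0.0, 1.0),
        rddt=np.clip(rddt, 0.0, 1.0),
        ks=ks,
        ko=ko,
    )


def sail_toc(
    leaf_rt: tuple[np.ndarray, np.ndarray],
    canopy: CanopyParamsSAIL,
    soil_spectrum: np.ndarray,
) -> np.ndarray:
    """Top-of-canopy bidirectional reflectance for a homogeneous canopy.

    ``soil_spectrum`` is the reference (bright/dry) soil reflectance; it is
    multiplied by the canopy's soil brightness coefficient.
    """
    rho, tau = leaf_rt
    soil_spectrum = np.asarray(soil_spectrum, dtype=float)
    if rho.shape != soil_spectrum.shape:
        raise ValueError("leaf and soil spectra are on different grids")
    lidf = campbell_lidf(canopy.LAD)
    fluxes = foursail(
        rho, tau, lidf,
        lai=canopy.LAI, hotspot=canopy.hotspot,
        tts=canopy.SZA, tto=canopy.OZA, psi=canopy.RAA,
        rsoil=canopy.soil_coeff * soil_spectrum,
    )
    return fluxes.toc(canopy.skyl)
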