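"""Reference evapotranspiration and its partition into soil evaporation and
crop transpiration.

Reference ET follows the FAO-56 Penman-Monteith formulation for the standard
clipped-grass surface (0.12 m height, surface resistance 70 s m-1, albedo
0.23), driven by daily weather. Potential crop ET is Kc * ET0; the canopy
fraction intercepted by leaves, 1 - exp(-Ke * LAI), receives transpiration
and the remainder is potential soil evaporation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date as Date

__all__ = [
    "WeatherRecord",
    "KcCurve",
    "penman_monteith_et0",
    "partition_et",
    "soil_evaporation_reduction",
]

STEFAN_BOLTZMANN = 4.903e-9  # MJ K-4 m-2 day-1
SOLAR_CONSTANT = 0.0820      # MJ m-2 min-1


@dataclass(frozen=True)
class WeatherRecord:
    """One day of weather forcing.

    Temperatures in deg C, relative humidity %, solar radiation MJ m-2 d-1,
    wind speed at 2 m in m s-1, precipitation mm.
    """

    date: Date
    tmax: float
    tmin: float
    rh_mean: float
    radiation: float
    wind: float
    precipitation: float

    def __post_init__(self) -> None:
        if self.tmax < self.tmin:
            raise ValueError(f"{self.date}: Tmax {self.tmax} < Tmin {self.tmin}")
        if not 0.0 <= self.rh_mean <= 100.0:
            raise ValueError(f"{self.date}: RH {self.rh_mean} outside [0, 100]")
        if min(self.radiation, self.wind, self.precipitation) < 0.0:
            raise ValueError(f"{self.date}: negative radiation/wind/precipitation")

    @property
    def tmean(self) -> float:
        return 0.5 * (self.tmax + self.tmin)


@dataclass(frozen=True)
class KcCurve:
    """FAO-56 style three-value crop coefficient curve.

    Interpolated as a trapezoid over relative development stage s in [0, 1]:
    K_ini up to s_dev, linear rise to K_mid at s_mid, flat to s_late, linear
    fall to K_end at maturity.
    """

    k_ini: float
    k_mid: float
    k_end: float
    s_dev: float = 0.25
    s_mid: float = 0.45
    s_late: float = 0.8

    def __post_init__(self) -> None:
        if min(self.k_ini, self.k_mid, self.k_end) <= 0.0:
            raise ValueError("crop coefficients must be positive")
        if not 0.0 < self.s_dev < self.s_mid < self.s_late < 1.0:
            raise ValueError("stage breakpoints must be ordered in (0, 1)")

    def at(self, stage: float) -> float:
        s = min(max(stage, 0.0), 1.0)
        if s <= self.s_dev:
            return self.k_ini
        if s <= self.s_mid:
            f = (s - self.s_dev) / (self.s_mid - self.s_dev)
            return self.k_ini + f * (self.k_mid - self.k_ini)
        if s <= self.s_late:
            return self.k_mid
        f = (s - self.s_late) / (1.0 - self.s_late)
        return self.k_mid + f * (self.k_end - self.k_mid)


def saturation_vapour_pressure(t: float) -> float:
    """e_s(T) in kPa (Tetens form used by FAO-56)."""
    return 0.6108 * math.exp(17.27 * t / (t + 237.3))


def extraterrestrial_radiation(latitude_deg: float, day_of_year: int) -> float:
    """Daily extraterrestrial radiation Ra (MJ m-2 d-1)."""
    phi = math.radians(latitude_deg)
    dr = 1.0 + 0.033 * math.cos(2.0 * math.pi * day_of_year / 365.0)
    delta = 0.409 * math.sin(2.0 * math.pi * day_of_year / 365.0 - 1.39)
    x = -math.tan(phi) * math.tan(delta)
    ws = math.acos(min(1.0, max(-1.0, x)))
    return (24.0 * 60.0 / math.pi * SOLAR_CONSTANT * dr
            * (ws * math.sin(phi) * math.sin(delta)
               + math.cos(phi) * math.cos(delta) * math.sin(ws)))


def daylength_hours(latitude_deg: float, day_of_year: int) -> float:
    """Astronomical daylength N (h)."""
    phi = math.radians(latitude_deg)
    delta = 0.409 * math.sin(2.0 * math.pi * day_of_year / 365.0 - 1.39)
    x = -math.tan(phi) * math.tan(delta)
    ws = math.acos(min(1.0, max(-1.0, x)))
    return 24.0 / math.pi * ws


def penman_monteith_et0(weather: WeatherRecord, latitude_deg: float,
                        elevation_m: float, day_of_year: int) -> float:
    """FAO-56 reference evapotranspiration ET0 (mm d-1), never negative.

    Vapour pressure deficit uses mean relative humidity applied to the mean
    of e_s(Tmax) and e_s(Tmin). Measured solar radiation above the clear-sky
    envelope is clipped to it.
    """
    tmean = weather.tmean
    P = 101.3 * ((293.0 - 0.0065 * elevation_m) / 293.0) ** 5.26  # kPa
    gamma = 0.000665 * P
    delta = (4098.0 * saturation_vapour_pressure(tmean)
             / (tmean + 237.3) ** 2)
    es = 0.5 * (saturation_vapour_pressure(weather.tmax)
                + saturation_vapour_pressure(weather.tmin))
    ea = weather.rh_mean / 100.0 * es

    Ra = extraterrestrial_radiation(latitude_deg, day_of_year)
    Rso = (0.75 + 2e-5 * elevation_m) * Ra
    Rs = min(weather.radiation, Rso) if Rso > 0.0 else 0.0
    Rns = (1.0 - 0.23) * Rs
    rel = Rs / Rso if Rso > 0.0 else 0.0
    tmaxk = weather.tmax + 273.16
    tmink = weather.tmin + 273.16
    Rnl = (STEFAN_BOLTZMANN * 0.5 * (tmaxk**4 + tmink**4)
           * (0.34 - 0.14 * math.sqrt(max(ea, 0.0)))
           * min(max(1.35 * rel - 0.35, 0.05), 1.0))
    Rn = Rns - Rnl

    u2 = weather.wind
    et0 = ((0.408 * delta * Rn
            + gamma * 900.0 / (tmean + 273.0) * u2 * (es - ea))
           / (delta + gamma * (1.0 + 0.34 * u2)))
    return max(et0, 0.0)


def partition_et(et0: float, kc: float, lai: float, ke: float = 0.6
                 ) -> tuple[float, float]:
    """Split potential crop ET into (potential soil evaporation, potential
    transpiration), both in the units of ``et0``.

    ETc = Kc*ET0; Tp = ETc*(1 - exp(-Ke*LAI)); Ep = ETc - Tp.
    """
    if lai < 0.0 or ke <= 0.0:
        raise ValueError("need LAI >= 0 and Ke > 0")
    etc = kc * et0
    tp = etc * (1.0 - math.exp(-ke * lai))
    return etc - tp, tp


def soil_evaporation_reduction(theta_top: float, theta_fc: float,
                               theta_r: float, shape: float = 3.0) -> float:
    """Soil-limited evaporation factor in (0, 1].

    Exponential resistance reduction below field capacity: full potential
    rate at or above theta_fc, exp(-shape * depletion) below it, where
    depletion is the relative dryness (theta_fc - theta)/(theta_fc - theta_r).
    """
    if theta_top >= theta_fc:
        return 1.0
    depletion = (theta_fc - theta_top) / max(theta_fc - theta_r, 1e-9)
    return math.exp(-shape * min(depletion, 1.0))
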