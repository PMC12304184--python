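"""Reference evapotranspiration via the modified Hargreaves method.

Daily ET0 (mm d⁻¹) needs only temperature, precipitation and solar geometry:

    ET0 = 0.0013 · 0.408 · RA · (Tavg + 17.0) · (TD − 0.0123·P)^0.76

with RA the extraterrestrial radiation (MJ m⁻² d⁻¹), Tavg the mean daily
temperature (°C), TD the diurnal temperature range (°C) and P daily
precipitation (mm).  RA follows the standard FAO-56 solar geometry:

    RA = (24·60/π) · Gsc · dr · [ωs·sin φ·sin δ + cos φ·cos δ·sin ωs]

with solar constant Gsc = 0.0820 MJ m⁻² min⁻¹, inverse relative Earth–Sun
distance dr, solar declination δ and sunset hour angle ωs.

The moisture term (TD − 0.0123·P) and the temperature term (Tavg + 17) are
floored at zero before use: the fractional exponent is undefined for
negative bases, and both floors correspond to physically shut-down
evaporative demand (the Droogers–Allen guard).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .errors import InvalidInputError
from .types import DailyMeteo, doy_of

__all__ = [
    "SolarGeometry",
    "solar_geometry",
    "extraterrestrial_radiation",
    "reference_et0",
    "et0_series",
]

#: Solar constant, MJ m⁻² min⁻¹.
GSC = 0.0820


@dataclass(frozen=True)
class SolarGeometry:
    """Solar geometry for one day at one latitude (angles in radians)."""

    doy: int
    latitude: float
    dr: float
    delta: float
    ws_angle: float
    gsc: float = GSC

    def __post_init__(self) -> None:
        if not 0.0 <= self.ws_angle <= math.pi:
            raise InvalidInputError(f"ws_angle={self.ws_angle} outside [0, pi]")
        if not 0.96 <= self.dr <= 1.04:
            raise InvalidInputError(f"dr={self.dr} outside [0.96, 1.04]")


def solar_geometry(doy: int, latitude_deg: float) -> SolarGeometry:
    """FAO-56 solar geometry: dr, declination and sunset hour angle.

    The arccos argument is clamped to [−1, 1] so polar night yields
    ωs = 0 and polar day ωs = π.
    """
    if not 1 <= doy <= 366:
        raise InvalidInputError(f"doy={doy} outside [1, 366]")
    if not -90.0 <= latitude_deg <= 90.0:
        raise InvalidInputError(f"latitude_deg={latitude_deg} outside [-90, 90]")
    phi = math.radians(latitude_deg)
    dr = 1.0 + 0.033 * math.cos(2.0 * math.pi * doy / 365.0)
    delta = 0.409 * math.sin(2.0 * math.pi * doy / 365.0 - 1.39)
    arg = -math.tan(phi) * math.tan(delta)
    ws_angle = math.acos(min(1.0, max(-1.0, arg)))
    return SolarGeometry(doy=doy, latitude=phi, dr=dr, delta=delta, ws_angle=ws_angle)


def extraterrestrial_radiation(geom: SolarGeometry) -> float:
    """Daily extraterrestrial radiation RA (MJ m⁻² d⁻¹), non-negative."""
    phi, delta, ws = geom.latitude, geom.delta, geom.ws_angle
    ra = (
        (24.0 * 60.0 / math.pi)
        * geom.gsc
        * geom.dr
        * (
            ws * math.sin(phi) * math.sin(delta)
            + math.cos(phi) * math.cos(delta) * math.sin(ws)
        )
    )
    return max(0.0, ra)


def reference_et0(ra: float, tavg: float, td: float, precip: float) -> float:
    """Modified-Hargreaves daily reference evapotranspiration (mm d⁻¹)."""
    if ra < 0:
        raise InvalidInputError(f"ra={ra} < 0")
    if td < 0:
        raise InvalidInputError(f"td={td} < 0 (diurnal range cannot be negative)")
    moisture = max(0.0, td - 0.0123 * precip)
    warmth = max(0.0, tavg + 17.0)
    return 0.0013 * 0.408 * ra * warmth * moisture**0.76


def et0_series(
    meteo: Sequence[DailyMeteo], latitude_deg: float
) -> list[DailyMeteo]:
    """Fill the ``et0`` field of a daily meteorology series.

    Uses TD = tmax − tmin and Tavg = (tmax + tmin)/2 when tavg is absent.
    """
    out: list[DailyMeteo] = []
    for day in meteo:
        if day.tmax < day.tmin:  # unreachable for validated records
            raise InvalidInputError(f"tmax < tmin on {day.date}")
        geom = solar_geometry(doy_of(day.date), latitude_deg)
        ra = extraterrestrial_radiation(geom)
        et0 = reference_et0(ra, day.mean_temperature, day.diurnal_range, day.precip)
        out.append(day.with_et0(et0))
    return out
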