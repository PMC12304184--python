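"""Domain records shared across the pipeline.

The unit of analysis is the *region-year*: one administrative region's growing
season in one calendar year.  Daily meteorology drives temperature stress and
reference evapotranspiration; 8-day remote-sensing composites (PAR, fAPAR,
NIR/SWIR reflectance) drive the light-use-efficiency NPP accumulation; the
region-year's observed yield closes the regression.

All records are frozen dataclasses validated on construction, so any list of
them is physically self-consistent by construction.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace

from .errors import InvalidInputError, SeasonIntegrityError

__all__ = [
    "DailyMeteo",
    "CompositeObservation",
    "SeasonSeries",
    "StressFactors",
    "YieldRecord",
    "FeatureVector",
    "SplitAssignment",
    "ModelScores",
    "doy_of",
]


def doy_of(date: dt.date) -> int:
    """1-based day of year."""
    return date.timetuple().tm_yday


def _check_unit(value: float, name: str) -> None:
    if not 0.0 <= value <= 1.0:
        raise InvalidInputError(f"{name}={value!r} outside [0, 1]")


@dataclass(frozen=True)
class DailyMeteo:
    """One day of forcing data at a site.

    Temperatures in °C, precipitation in mm d⁻¹, solar radiation in
    MJ m⁻² d⁻¹, wind in m s⁻¹, relative humidity in %, soil-wetness layers as
    fractions of saturation.  ``et0`` (mm d⁻¹) is filled by the
    evapotranspiration module.
    """

    date: dt.date
    tmax: float
    tmin: float
    precip: float
    solar: float
    wind: float
    rh: float
    surface_soil_wetness: float
    profile_soil_moisture: float
    root_zone_wetness: float
    tavg: float | None = None
    et0: float | None = None

    def __post_init__(self) -> None:
        if self.tmax < self.tmin:
            raise InvalidInputError(
                f"tmax < tmin ({self.tmax} < {self.tmin}) on {self.date}"
            )
        if self.precip < 0:
            raise InvalidInputError(f"negative precip on {self.date}")
        if self.solar < 0:
            raise InvalidInputError(f"negative solar radiation on {self.date}")
        if self.wind < 0:
            raise InvalidInputError(f"negative wind speed on {self.date}")
        if not 0.0 <= self.rh <= 100.0:
            raise InvalidInputError(f"rh={self.rh} outside [0, 100] on {self.date}")
        for name in ("surface_soil_wetness", "profile_soil_moisture", "root_zone_wetness"):
            _check_unit(getattr(self, name), name)
        if self.tavg is not None and not (self.tmin <= self.tavg <= self.tmax):
            raise InvalidInputError(
                f"tavg={self.tavg} outside [tmin, tmax] on {self.date}"
            )

    @property
    def mean_temperature(self) -> float:
        """tavg when recorded, else the midrange (tmax + tmin) / 2."""
        return self.tavg if self.tavg is not None else 0.5 * (self.tmax + self.tmin)

    @property
    def diurnal_range(self) -> float:
        return self.tmax - self.tmin

    def with_et0(self, et0: float) -> "DailyMeteo":
        return replace(self, et0=et0)


@dataclass(frozen=True)
class CompositeObservation:
    """One 8-day (or truncated final) remote-sensing composite.

    ``par_daily_mean`` is the mean daily incident PAR (MJ m⁻² d⁻¹) over the
    composite window, so the window's energy total is
    ``par_daily_mean * n_days`` — the Δt of the NPP sum is explicit.
    """

    start_doy: int
    n_days: int
    par_daily_mean: float
    fapar: float
    nir: float
    swir: float

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise InvalidInputError(f"composite n_days={self.n_days} < 1")
        if self.par_daily_mean < 0:
            raise InvalidInputError("negative par_daily_mean")
        _check_unit(self.fapar, "fapar")
        _check_unit(self.nir, "nir")
        _check_unit(self.swir, "swir")

    @property
    def end_doy(self) -> int:
        return self.start_doy + self.n_days - 1


@dataclass(frozen=True)
class SeasonSeries:
    """One region-year's growing season: daily meteorology + composite tiling.

    Composites must be ordered, non-overlapping and jointly cover
    [season_start, season_end]; only the final composite may be shorter than
    8 days.  ``meteo`` may be empty when only reflectance-driven quantities
    are needed, but temperature stress requires it.
    """

    region_id: str
    year: int
    season_start: dt.date
    season_end: dt.date
    meteo: tuple[DailyMeteo, ...] = ()
    composites: tuple[CompositeObservation, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "meteo", tuple(self.meteo))
        object.__setattr__(self, "composites", tuple(self.composites))
        if self.season_end < self.season_start:
            raise SeasonIntegrityError(
                f"{self.region_id}/{self.year}: season_end before season_start"
            )
        if self.composites:
            self._check_tiling()
        if self.meteo:
            self._check_meteo()

    def _check_tiling(self) -> None:
        start = doy_of(self.season_start)
        end = doy_of(self.season_end)
        expected = start
        for i, comp in enumerate(self.composites):
            if comp.start_doy != expected:
                raise SeasonIntegrityError(
                    f"{self.region_id}/{self.year}: composite {i} starts at DOY "
                    f"{comp.start_doy}, expected {expected} (overlap or gap)"
                )
            if comp.n_days > 8:
                raise SeasonIntegrityError(
                    f"{self.region_id}/{self.year}: composite {i} spans "
                    f"{comp.n_days} days > 8"
                )
            if comp.n_days < 8 and i != len(self.composites) - 1:
                raise SeasonIntegrityError(
                    f"{self.region_id}/{self.year}: non-final composite {i} "
                    f"spans only {comp.n_days} days"
                )
            expected = comp.start_doy + comp.n_days
        if expected != end + 1:
            raise SeasonIntegrityError(
                f"{self.region_id}/{self.year}: composites end at DOY "
                f"{expected - 1}, season ends at DOY {end}"
            )

    def _check_meteo(self) -> None:
        if len(self.meteo) != self.n_days:
            raise SeasonIntegrityError(
                f"{self.region_id}/{self.year}: {len(self.meteo)} meteorology "
                f"days for a {self.n_days}-day season"
            )
        day = self.season_start
        for rec in self.meteo:
            if rec.date != day:
                raise SeasonIntegrityError(
                    f"{self.region_id}/{self.year}: meteorology day {rec.date} "
                    f"out of order (expected {day})"
                )
            day += dt.timedelta(days=1)

    @property
    def n_days(self) -> int:
        return (self.season_end - self.season_start).days + 1

    def with_meteo(self, meteo: tuple[DailyMeteo, ...]) -> "SeasonSeries":
        return replace(self, meteo=tuple(meteo))

    def composite_meteo(self, index: int) -> tuple[DailyMeteo, ...]:
        """The daily meteorology rows falling inside composite ``index``."""
        if not self.meteo:
            raise InvalidInputError(
                f"{self.region_id}/{self.year}: season has no meteorology"
            )
        comp = self.composites[index]
        offset = comp.start_doy - doy_of(self.season_start)
        return self.meteo[offset : offset + comp.n_days]


@dataclass(frozen=True)
class StressFactors:
    """Per-composite environmental scalars of the LUE model."""

    composite_index: int
    lswi: float
    ws: float
    ts: float
    ps: float
    epsilon: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.lswi <= 1.0:
            raise InvalidInputError(f"lswi={self.lswi} outside [-1, 1]")
        for name in ("ws", "ts", "ps"):
            _check_unit(getattr(self, name), name)
        if self.epsilon < 0:
            raise InvalidInputError(f"epsilon={self.epsilon} < 0")


@dataclass(frozen=True)
class YieldRecord:
    """One region-year: seasonal ΣNPP, observed yield, model predictions."""

    region_id: str
    year: int
    sum_npp: float
    observed_yield: float | None = None
    predictions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sum_npp < 0:
            raise InvalidInputError(
                f"{self.region_id}/{self.year}: negative sum_npp"
            )
        if self.observed_yield is not None and self.observed_yield <= 0:
            raise InvalidInputError(
                f"{self.region_id}/{self.year}: non-positive observed yield"
            )

    def with_prediction(self, model: str, value: float) -> "YieldRecord":
        preds = dict(self.predictions)
        preds[model] = value
        return replace(self, predictions=preds)


#: Canonical order of the nine seasonal meteorology features.
FEATURE_NAMES: tuple[str, ...] = (
    "tmax",
    "tmin",
    "precip",
    "solar",
    "wind",
    "rh",
    "surface_soil_wetness",
    "profile_soil_moisture",
    "root_zone_wetness",
)


@dataclass(frozen=True)
class FeatureVector:
    """Season-mean meteorology features for one region-year, plus yield."""

    region_id: str
    year: int
    features: tuple[float, ...]
    target: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "features", tuple(float(x) for x in self.features))
        if len(self.features) != len(FEATURE_NAMES):
            raise InvalidInputError(
                f"{self.region_id}/{self.year}: expected {len(FEATURE_NAMES)} "
                f"features, got {len(self.features)}"
            )
        if any(not math.isfinite(x) for x in self.features):
            raise InvalidInputError(
                f"{self.region_id}/{self.year}: non-finite feature value"
            )


@dataclass(frozen=True)
class SplitAssignment:
    """Exact disjoint partition of row indices into train/validation/test."""

    train: tuple[int, ...]
    validation: tuple[int, ...]
    test: tuple[int, ...]
    seed: int

    def __post_init__(self) -> None:
        parts = (*self.train, *self.validation, *self.test)
        n = len(parts)
        if sorted(parts) != list(range(n)):
            raise InvalidInputError("split is not an exact partition of 0..n-1")

    @property
    def n(self) -> int:
        return len(self.train) + len(self.validation) + len(self.test)

    def split_of(self, index: int) -> str:
        if index in self.train:
            return "calibration"
        if index in self.validation:
            return "validation"
        return "test"


@dataclass(frozen=True)
class ModelScores:
    """R²/RMSE/Pearson-r for one (model, crop, split) cell."""

    model: str
    crop: str
    split: str
    r2: float
    rmse: float
    pearson_r: float
    n: int

    def __post_init__(self) -> None:
        if self.rmse < 0:
            raise InvalidInputError("rmse < 0")
        if self.n < 2:
            raise InvalidInputError("n < 2")
        if not -1.0 - 1e-12 <= self.pearson_r <= 1.0 + 1e-12:
            raise InvalidInputError(f"pearson_r={self.pearson_r} outside [-1, 1]")
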