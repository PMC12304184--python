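"""Seeded synthetic region-year datasets with known ground truth.

Emulates the statistical structure of the real inputs the pipeline is built
for — daily meteorology tables, 8-day growing-season remote-sensing
composites, and region-year observed yields — so every downstream stage is
testable without any download:

* Meteorology: sinusoidal seasonal cycles for temperature and solar
  radiation plus seeded Gaussian noise, an intermittent (rain-day indicator ×
  gamma amount) precipitation process, and soil-wetness layers nudged by
  recent rainfall.  Daily maximum temperature is kept inside the observed
  midwest plausibility envelope [−19.23, 41.31] °C.
* Composites: fAPAR follows a product of green-up and senescence logistics
  scaled to the configured peak; NIR/SWIR reflectances are constructed so
  LSWI rises from a low early-season base to a single mid-season maximum;
  PAR daily means track 45 % of simulated solar radiation, clipped to the
  configured range.
* Yields: observed_yield = truth_a·ΣNPP + truth_b + Normal(0, yield_noise_sd),
  with ΣNPP computed by the actual stress/NPP pipeline on the generated
  composites — so calibration can be checked against the known truth.

Every (region, year) has its own pseudo-random stream derived from the
master seed, so regions are generated independently and reproducibly:
identical configs give bit-identical datasets.

Composite greenness is weakly coupled to the same region-year's season-total
precipitation and mean temperature, so seasonal meteorology features carry
genuine (if modest) signal about yield.
"""

from __future__ import annotations

import datetime as dt
import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidConfigError
from .npp import DEFAULT_CONSTANTS, accumulate_npp
from .stress import CropStressParams, season_stress_factors
from .types import (
    CompositeObservation,
    DailyMeteo,
    FeatureVector,
    SeasonSeries,
    YieldRecord,
    doy_of,
)

__all__ = [
    "SimulationConfig",
    "TMAX_ENVELOPE",
    "region_ids",
    "generate_meteorology",
    "generate_composites",
    "generate_season",
    "generate_yield_dataset",
    "make_linear_feature_dataset",
]

#: Plausibility bounds for daily maximum temperature (°C), the observed
#: midwest extremes used to clip the simulated series.
TMAX_ENVELOPE = (-19.23, 41.31)

#: Crop-specific generator defaults: (fapar_peak, par range MJ m⁻² d⁻¹).
#: Chosen so that the pipeline's ΣNPP maps through the published regression
#: constants to realistic yields (corn ≈ 7–15, soybean ≈ 2.5–4.4 ton/ha).
_CROP_CANOPY_DEFAULTS: dict[str, tuple[float, tuple[float, float]]] = {
    "corn": (0.95, (7.0, 12.0)),
    "soybean": (0.55, (6.0, 10.0)),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic dataset (including the truth)."""

    crop: str = "corn"
    n_regions: int = 10
    years: tuple[int, ...] = tuple(range(2015, 2025))
    seed: int = 0
    yield_noise_sd: float = 0.3
    fapar_peak: float = 0.95
    par_daily_mean_range: tuple[float, float] = (7.0, 12.0)
    reflectance_noise_sd: float = 0.01
    truth_a: float = 0.12
    truth_b: float = 0.739
    season_start_md: tuple[int, int] = (5, 20)
    season_end_md: tuple[int, int] = (9, 30)

    def __post_init__(self) -> None:
        object.__setattr__(self, "years", tuple(self.years))
        object.__setattr__(
            self, "par_daily_mean_range", tuple(self.par_daily_mean_range)
        )
        if self.crop not in DEFAULT_CONSTANTS:
            raise InvalidConfigError(f"unknown crop {self.crop!r}")
        if self.n_regions < 1:
            raise InvalidConfigError("n_regions must be positive")
        if not self.years:
            raise InvalidConfigError("years must be non-empty")
        if self.seed < 0:
            raise InvalidConfigError("seed must be non-negative")
        if self.yield_noise_sd < 0:
            raise InvalidConfigError("yield_noise_sd must be >= 0")
        if not 0.0 < self.fapar_peak <= 1.0:
            raise InvalidConfigError("fapar_peak must lie in (0, 1]")
        low, high = self.par_daily_mean_range
        if not low < high:
            raise InvalidConfigError("par range must satisfy low < high")
        if low < 0:
            raise InvalidConfigError("par range must be non-negative")
        if self.reflectance_noise_sd < 0:
            raise InvalidConfigError("reflectance_noise_sd must be >= 0")
        if not (math.isfinite(self.truth_a) and math.isfinite(self.truth_b)):
            raise InvalidConfigError("truth constants must be finite")
        for year in self.years:
            if self.season_end(year) < self.season_start(year):
                raise InvalidConfigError("season window must have positive length")

    @classmethod
    def for_crop(cls, crop: str, **overrides) -> "SimulationConfig":
        """Crop-appropriate defaults: canopy peak, PAR range, truth constants."""
        if crop not in DEFAULT_CONSTANTS:
            raise InvalidConfigError(f"unknown crop {crop!r}")
        peak, par_range = _CROP_CANOPY_DEFAULTS[crop]
        a, b = DEFAULT_CONSTANTS[crop]
        base = dict(
            crop=crop,
            fapar_peak=peak,
            par_daily_mean_range=par_range,
            truth_a=a,
            truth_b=b,
        )
        base.update(overrides)
        return cls(**base)

    def season_start(self, year: int) -> dt.date:
        return dt.date(year, *self.season_start_md)

    def season_end(self, year: int) -> dt.date:
        return dt.date(year, *self.season_end_md)

    def to_dict(self) -> dict:
        return {
            "crop": self.crop,
            "n_regions": self.n_regions,
            "years": list(self.years),
            "seed": self.seed,
            "yield_noise_sd": self.yield_noise_sd,
            "fapar_peak": self.fapar_peak,
            "par_daily_mean_range": list(self.par_daily_mean_range),
            "reflectance_noise_sd": self.reflectance_noise_sd,
            "truth_a": self.truth_a,
            "truth_b": self.truth_b,
            "season_start_md": list(self.season_start_md),
            "season_end_md": list(self.season_end_md),
        }


def region_ids(config: SimulationConfig) -> list[str]:
    return [f"R{i + 1:03d}" for i in range(config.n_regions)]


_STREAM_METEO, _STREAM_COMPOSITE, _STREAM_YIELD = 0, 1, 2


def _rng(config: SimulationConfig, region_id: str, year: int, stream: int):
    """Independent, reproducible stream per (region, year, purpose)."""
    key = zlib.crc32(region_id.encode("utf-8"))
    return np.random.default_rng(
        np.random.SeedSequence([config.seed, key, year, stream])
    )


def _season_doys(config: SimulationConfig, year: int) -> np.ndarray:
    start, end = config.season_start(year), config.season_end(year)
    return np.arange(doy_of(start), doy_of(end) + 1)


def _meteo_arrays(config: SimulationConfig, region_id: str, year: int) -> dict:
    rng = _rng(config, region_id, year, _STREAM_METEO)
    doy = _season_doys(config, year)
    n = doy.size

    # corn-belt summer climatology: July peak tmax ~32 °C, season mean ~29 °C
    tmax_clim = 23.5 + 8.5 * np.cos(2.0 * np.pi * (doy - 199) / 365.0)
    tmax = np.clip(tmax_clim + rng.normal(0.0, 2.5, n), *TMAX_ENVELOPE)
    td = np.maximum(0.5, rng.normal(11.0, 2.5, n))
    tmin = tmax - td

    precip = rng.binomial(1, 0.30, n) * rng.gamma(1.2, 7.0, n)
    solar = np.clip(
        22.0 + 6.0 * np.cos(2.0 * np.pi * (doy - 172) / 365.0) + rng.normal(0, 3.0, n),
        0.5,
        None,
    )
    rh = np.clip(rng.normal(72.0, 10.0, n), 5.0, 100.0)
    wind = np.abs(rng.normal(3.5, 1.5, n))

    base = float(np.clip(rng.normal(0.55, 0.08), 0.15, 0.90))
    recent = np.convolve(precip, np.ones(3) / 3.0, mode="same")
    surface = np.clip(base + 0.004 * (recent - 7.0) + rng.normal(0, 0.05, n), 0.0, 1.0)
    running_mean = np.cumsum(precip) / np.arange(1, n + 1)
    profile = np.clip(base + 0.002 * (running_mean - 2.5) + rng.normal(0, 0.02, n), 0.0, 1.0)
    root = np.clip(0.5 * surface + 0.5 * profile + rng.normal(0, 0.01, n), 0.0, 1.0)

    return {
        "doy": doy,
        "tmax": tmax,
        "tmin": tmin,
        "precip": precip,
        "solar": solar,
        "rh": rh,
        "wind": wind,
        "surface": surface,
        "profile": profile,
        "root": root,
    }


def generate_meteorology(
    config: SimulationConfig, region_id: str, year: int
) -> list[DailyMeteo]:
    """One region-year of daily growing-season meteorology."""
    arr = _meteo_arrays(config, region_id, year)
    start = config.season_start(year)
    out = []
    for i in range(arr["doy"].size):
        out.append(
            DailyMeteo(
                date=start + dt.timedelta(days=i),
                tmax=float(arr["tmax"][i]),
                tmin=float(arr["tmin"][i]),
                tavg=float(0.5 * (arr["tmax"][i] + arr["tmin"][i])),
                precip=float(arr["precip"][i]),
                solar=float(arr["solar"][i]),
                wind=float(arr["wind"][i]),
                rh=float(arr["rh"][i]),
                surface_soil_wetness=float(arr["surface"][i]),
                profile_soil_moisture=float(arr["profile"][i]),
                root_zone_wetness=float(arr["root"][i]),
            )
        )
    return out


def composite_tiling(n_days_total: int) -> list[tuple[int, int]]:
    """(offset, n_days) tiles: full 8-day composites plus a truncated tail."""
    if n_days_total < 1:
        raise InvalidConfigError("season must span at least one day")
    tiles = []
    offset = 0
    while offset < n_days_total:
        tiles.append((offset, min(8, n_days_total - offset)))
        offset += 8
    return tiles


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_composites(
    config: SimulationConfig, region_id: str, year: int
) -> list[CompositeObservation]:
    """One region-year of 8-day composites (PAR, fAPAR, NIR, SWIR)."""
    met = _meteo_arrays(config, region_id, year)
    rng = _rng(config, region_id, year, _STREAM_COMPOSITE)
    doy = met["doy"]
    n = doy.size
    t = np.arange(n, dtype=float)

    # single-peak canopy shape: green-up logistic x senescence logistic
    shape = _logistic(0.18 * (t - 0.19 * n)) * _logistic(-0.12 * (t - 0.82 * n))
    shape = shape / shape.max()

    precip_anom = float(np.clip((met["precip"].sum() - 330.0) / 150.0, -1.5, 1.5))
    tavg = 0.5 * (met["tmax"] + met["tmin"])
    temp_anom = float(np.clip((tavg.mean() - 24.7) / 2.0, -1.5, 1.5))

    peak = float(
        np.clip(
            config.fapar_peak
            * (1.0 + 0.06 * precip_anom + 0.03 * temp_anom + rng.normal(0, 0.05)),
            0.05,
            1.0,
        )
    )
    lswi_amp = float(
        np.clip(0.45 * (1.0 + 0.15 * precip_anom) + rng.normal(0, 0.03), 0.10, 0.80)
    )

    low, high = config.par_daily_mean_range
    tiles = composite_tiling(n)
    out = []
    for offset, n_days in tiles:
        mid = offset + (n_days - 1) // 2
        fapar = float(np.clip(peak * shape[mid] + rng.normal(0, 0.01), 0.0, 1.0))
        lswi_target = 0.05 + lswi_amp * shape[mid]
        total = 0.55  # NIR + SWIR kept fixed; LSWI sets the partition
        nir = total * (1.0 + lswi_target) / 2.0 + rng.normal(0, config.reflectance_noise_sd)
        swir = total * (1.0 - lswi_target) / 2.0 + rng.normal(0, config.reflectance_noise_sd)
        nir = float(np.clip(nir, 0.02, 0.98))
        swir = float(np.clip(swir, 0.02, 0.98))
        par = float(np.clip(0.45 * met["solar"][offset : offset + n_days].mean(), low, high))
        out.append(
            CompositeObservation(
                start_doy=int(doy[offset]),
                n_days=n_days,
                par_daily_mean=par,
                fapar=fapar,
                nir=nir,
                swir=swir,
            )
        )
    return out


def generate_season(
    config: SimulationConfig, region_id: str, year: int
) -> SeasonSeries:
    """A full SeasonSeries: daily meteorology plus the composite tiling."""
    return SeasonSeries(
        region_id=region_id,
        year=year,
        season_start=config.season_start(year),
        season_end=config.season_end(year),
        meteo=tuple(generate_meteorology(config, region_id, year)),
        composites=tuple(generate_composites(config, region_id, year)),
    )


def generate_yield_dataset(
    config: SimulationConfig,
    stress_params: CropStressParams | None = None,
    *,
    seasons: list[SeasonSeries] | None = None,
) -> list[YieldRecord]:
    """Region-year records with ΣNPP from the actual pipeline and noisy yields.

    observed_yield = truth_a·ΣNPP + truth_b + Normal(0, yield_noise_sd); the
    record keeps the true ΣNPP, so ordinary least squares on
    (sum_npp, observed_yield) should recover (truth_a, truth_b).
    """
    stress_params = stress_params or CropStressParams()
    records = []
    season_iter = (
        seasons
        if seasons is not None
        else (
            generate_season(config, rid, year)
            for rid in region_ids(config)
            for year in config.years
        )
    )
    for season in season_iter:
        stress = season_stress_factors(season, stress_params)
        sum_npp = accumulate_npp(season.composites, stress)
        noise = (
            float(
                _rng(config, season.region_id, season.year, _STREAM_YIELD).normal(
                    0.0, config.yield_noise_sd
                )
            )
            if config.yield_noise_sd > 0
            else 0.0
        )
        records.append(
            YieldRecord(
                region_id=season.region_id,
                year=season.year,
                sum_npp=sum_npp,
                observed_yield=config.truth_a * sum_npp + config.truth_b + noise,
            )
        )
    return records


def make_linear_feature_dataset(
    n: int,
    seed: int,
    noise_sd: float = 0.1,
    coefficients: np.ndarray | None = None,
    intercept: float = 8.0,
) -> list[FeatureVector]:
    """Standard-normal features with a linear target, for protocol checks.

    yield = intercept + coefficients·x + Normal(0, noise_sd).  Default
    coefficients are unit weights on all nine features.
    """
    rng = np.random.default_rng(seed)
    coef = (
        np.ones(9) if coefficients is None else np.asarray(coefficients, dtype=float)
    )
    x = rng.normal(0.0, 1.0, size=(n, coef.size))
    y = intercept + x @ coef + rng.normal(0.0, noise_sd, size=n)
    return [
        FeatureVector(
            region_id=f"S{i:04d}", year=2000, features=tuple(x[i]), target=float(y[i])
        )
        for i in range(n)
    ]
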