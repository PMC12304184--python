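import datetime as dt

import pytest
from hypothesis import settings

from lueyield import CompositeObservation, DailyMeteo, SeasonSeries

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


def _day(date, tmax, tmin, precip=0.0, solar=22.0):
    return DailyMeteo(
        date=date,
        tmax=tmax,
        tmin=tmin,
        precip=precip,
        solar=solar,
        wind=3.0,
        rh=70.0,
        surface_soil_wetness=0.5,
        profile_soil_moisture=0.5,
        root_zone_wetness=0.5,
    )


@pytest.fixture
def toy_season() -> SeasonSeries:
    """Five 8-day composites (40-day season from June 1) with flat meteorology.

    Composite temperatures ramp so Ts varies; NIR/SWIR chosen so LSWI rises
    then falls with the interior maximum at composite 2.
    """
    start = dt.date(2021, 6, 1)  # DOY 152
    lswi_values = [0.10, 0.35, 0.55, 0.40, 0.20]
    comps = []
    for i, lswi in enumerate(lswi_values):
        total = 0.5
        comps.append(
            CompositeObservation(
                start_doy=152 + 8 * i,
                n_days=8,
                par_daily_mean=10.0,
                fapar=0.3 + 0.1 * i,
                nir=total * (1 + lswi) / 2,
                swir=total * (1 - lswi) / 2,
            )
        )
    meteo = []
    for d in range(40):
        comp = d // 8
        tmax = 26.0 + 2.0 * comp  # composite-mean tmax: 26, 28, 30, 32, 34
        meteo.append(_day(start + dt.timedelta(days=d), tmax=tmax, tmin=tmax - 12.0))
    return SeasonSeries(
        region_id="TOY",
        year=2021,
        season_start=start,
        season_end=start + dt.timedelta(days=39),
        meteo=tuple(meteo),
        composites=tuple(comps),
    )


@pytest.fixture
def flat_day_factory():
    return _day
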