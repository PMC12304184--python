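"""Season-mean meteorology features for the neural-network baseline.

Each region-year is summarised by the growing-season means of the nine daily
forcing variables (tmax, tmin, precipitation, solar radiation, wind,
relative humidity, surface soil wetness, profile soil moisture, root-zone
wetness), in that fixed order.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .errors import InvalidInputError
from .types import DailyMeteo, FeatureVector, SeasonSeries

__all__ = ["season_feature_vector", "build_feature_table"]


def season_feature_vector(
    region_id: str,
    year: int,
    meteo: Sequence[DailyMeteo],
    target: float | None = None,
) -> FeatureVector:
    """Nine season-mean features for one region-year."""
    if not meteo:
        raise InvalidInputError(f"{region_id}/{year}: no meteorology days")
    cols = np.asarray(
        [
            [
                d.tmax,
                d.tmin,
                d.precip,
                d.solar,
                d.wind,
                d.rh,
                d.surface_soil_wetness,
                d.profile_soil_moisture,
                d.root_zone_wetness,
            ]
            for d in meteo
        ],
        dtype=float,
    )
    return FeatureVector(
        region_id=region_id,
        year=year,
        features=tuple(cols.mean(axis=0).tolist()),
        target=target,
    )


def build_feature_table(
    seasons: Sequence[SeasonSeries],
    targets: Sequence[float | None] | None = None,
) -> list[FeatureVector]:
    """Feature rows for many seasons, index-aligned with optional targets."""
    if targets is not None and len(targets) != len(seasons):
        raise InvalidInputError("targets not index-aligned with seasons")
    return [
        season_feature_vector(
            s.region_id,
            s.year,
            s.meteo,
            None if targets is None else targets[i],
        )
        for i, s in enumerate(seasons)
    ]
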