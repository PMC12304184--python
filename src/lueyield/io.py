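"""On-disk formats: CSV readers/writers binding the pipeline stages together.

All interchange is plain CSV (the real upstream products — daily meteorology
tables and 8-day composite tables — are tabular exports), with ISO-8601
dates and 1-based day-of-year.  Writers produce files their readers accept.

Layouts
-------
meteorology.csv : region, year, date, tmax_c, tmin_c, tavg_c, precip_mm,
                  solar_mj_m2, wind_ms, rh_pct, surface_sw, profile_sm,
                  rootzone_sw [, et0_mm]
                  (region/year/tavg_c/et0_mm optional)
composites.csv  : region, year, start_doy, n_days, par_mj_m2_d, fapar, nir, swir
features.csv    : region, year, <nine feature columns>, yield_t_ha
yields.csv      : region, year, sum_npp, observed_yield [, pred_<model>...]
scores.csv      : model, crop, split, r2, rmse, pearson_r, n
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import InvalidInputError
from .types import (
    FEATURE_NAMES,
    CompositeObservation,
    DailyMeteo,
    FeatureVector,
    ModelScores,
    SeasonSeries,
    YieldRecord,
    doy_of,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_meteorology_csv",
    "read_meteorology_groups",
    "write_meteorology_csv",
    "read_composites_csv",
    "write_composites_csv",
    "attach_meteorology",
    "read_features_csv",
    "write_features_csv",
    "read_yields_csv",
    "write_yields_csv",
    "write_scores",
    "write_simulation",
]

_METEO_REQUIRED = [
    "date",
    "tmax_c",
    "tmin_c",
    "precip_mm",
    "solar_mj_m2",
    "wind_ms",
    "rh_pct",
    "surface_sw",
    "profile_sm",
    "rootzone_sw",
]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InvalidInputError(f"{path}: missing required column(s) {missing}")


def _meteo_from_row(row, row_no: int, path) -> DailyMeteo:
    try:
        date = dt.date.fromisoformat(str(row["date"]))
    except ValueError as exc:
        raise InvalidInputError(f"{path} row {row_no}, column 'date': {exc}") from exc
    tavg = row.get("tavg_c")
    et0 = row.get("et0_mm")
    try:
        return DailyMeteo(
            date=date,
            tmax=float(row["tmax_c"]),
            tmin=float(row["tmin_c"]),
            tavg=None if tavg is None or pd.isna(tavg) else float(tavg),
            precip=float(row["precip_mm"]),
            solar=float(row["solar_mj_m2"]),
            wind=float(row["wind_ms"]),
            rh=float(row["rh_pct"]),
            surface_soil_wetness=float(row["surface_sw"]),
            profile_soil_moisture=float(row["profile_sm"]),
            root_zone_wetness=float(row["rootzone_sw"]),
            et0=None if et0 is None or pd.isna(et0) else float(et0),
        )
    except InvalidInputError as exc:
        raise InvalidInputError(f"{path} row {row_no}: {exc}") from exc


def read_meteorology_csv(path) -> list[DailyMeteo]:
    """A single site's daily meteorology, date-sorted and validated.

    For multi-region files use :func:`read_meteorology_groups`.
    """
    groups = read_meteorology_groups(path)
    if len(groups) > 1:
        raise InvalidInputError(
            f"{path}: contains {len(groups)} (region, year) groups; "
            "use read_meteorology_groups"
        )
    return next(iter(groups.values()), [])


def read_meteorology_groups(path) -> dict[tuple[str, int], list[DailyMeteo]]:
    """Daily meteorology grouped by (region, year); single-group files get key ('', year)."""
    df = pd.read_csv(path, dtype={"date": str}, float_precision="round_trip")
    if df.empty:
        logger.warning("%s: empty meteorology data section", path)
        return {}
    _require_columns(df, _METEO_REQUIRED, path)
    out: dict[tuple[str, int], list[DailyMeteo]] = {}
    for row_no, row in enumerate(df.to_dict("records"), start=2):
        rec = _meteo_from_row(row, row_no, path)
        region = str(row.get("region", "") or "")
        year = int(row.get("year", rec.date.year))
        out.setdefault((region, year), []).append(rec)
    for key in out:
        out[key].sort(key=lambda r: r.date)
    return out


def write_meteorology_csv(
    path, groups: Mapping[tuple[str, int], Sequence[DailyMeteo]]
) -> None:
    rows = []
    for (region, year), days in groups.items():
        for d in days:
            rows.append(
                {
                    "region": region,
                    "year": year,
                    "date": d.date.isoformat(),
                    "tmax_c": d.tmax,
                    "tmin_c": d.tmin,
                    "tavg_c": "" if d.tavg is None else d.tavg,
                    "precip_mm": d.precip,
                    "solar_mj_m2": d.solar,
                    "wind_ms": d.wind,
                    "rh_pct": d.rh,
                    "surface_sw": d.surface_soil_wetness,
                    "profile_sm": d.profile_soil_moisture,
                    "rootzone_sw": d.root_zone_wetness,
                    "et0_mm": "" if d.et0 is None else d.et0,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


_COMPOSITE_COLUMNS = [
    "region",
    "year",
    "start_doy",
    "n_days",
    "par_mj_m2_d",
    "fapar",
    "nir",
    "swir",
]


def read_composites_csv(path) -> list[SeasonSeries]:
    """Composite table grouped into per-(region, year) seasons.

    The tiling invariants (ordered, gap-free, only the final composite short)
    are enforced by :class:`SeasonSeries` construction.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        logger.warning("%s: empty composites data section", path)
        return []
    _require_columns(df, _COMPOSITE_COLUMNS, path)
    seasons = []
    for (region, year), grp in df.groupby(["region", "year"], sort=True):
        grp = grp.sort_values("start_doy")
        if grp["start_doy"].duplicated().any():
            raise InvalidInputError(
                f"{path}: duplicated start_doy in season {region}/{year}"
            )
        comps = tuple(
            CompositeObservation(
                start_doy=int(r.start_doy),
                n_days=int(r.n_days),
                par_daily_mean=float(r.par_mj_m2_d),
                fapar=float(r.fapar),
                nir=float(r.nir),
                swir=float(r.swir),
            )
            for r in grp.itertuples()
        )
        year = int(year)
        jan1 = dt.date(year, 1, 1)
        start = jan1 + dt.timedelta(days=comps[0].start_doy - 1)
        end = jan1 + dt.timedelta(days=comps[-1].end_doy - 1)
        seasons.append(
            SeasonSeries(
                region_id=str(region),
                year=year,
                season_start=start,
                season_end=end,
                composites=comps,
            )
        )
    return seasons


def write_composites_csv(path, seasons: Sequence[SeasonSeries]) -> None:
    rows = [
        {
            "region": s.region_id,
            "year": s.year,
            "start_doy": c.start_doy,
            "n_days": c.n_days,
            "par_mj_m2_d": c.par_daily_mean,
            "fapar": c.fapar,
            "nir": c.nir,
            "swir": c.swir,
        }
        for s in seasons
        for c in s.composites
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def attach_meteorology(
    seasons: Sequence[SeasonSeries],
    groups: Mapping[tuple[str, int], Sequence[DailyMeteo]],
) -> list[SeasonSeries]:
    """Join composite seasons with their daily meteorology by (region, year)."""
    out = []
    for s in seasons:
        key = (s.region_id, s.year)
        if key not in groups:
            raise InvalidInputError(f"no meteorology for season {s.region_id}/{s.year}")
        days = [
            d for d in groups[key] if s.season_start <= d.date <= s.season_end
        ]
        out.append(s.with_meteo(tuple(days)))
    return out


def read_features_csv(path) -> list[FeatureVector]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["region", "year", *FEATURE_NAMES], path)
    rows = []
    for r in df.to_dict("records"):
        target = r.get("yield_t_ha")
        rows.append(
            FeatureVector(
                region_id=str(r["region"]),
                year=int(r["year"]),
                features=tuple(float(r[name]) for name in FEATURE_NAMES),
                target=None if target is None or pd.isna(target) else float(target),
            )
        )
    return rows


def write_features_csv(path, rows: Sequence[FeatureVector]) -> None:
    pd.DataFrame(
        [
            {
                "region": r.region_id,
                "year": r.year,
                **dict(zip(FEATURE_NAMES, r.features)),
                "yield_t_ha": "" if r.target is None else r.target,
            }
            for r in rows
        ]
    ).to_csv(path, index=False)


def read_yields_csv(path) -> list[YieldRecord]:
    """Region-year records; every ``pred_<model>`` column becomes a prediction."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["region", "year", "sum_npp"], path)
    pred_cols = [c for c in df.columns if c.startswith("pred_")]
    records = []
    for r in df.to_dict("records"):
        obs = r.get("observed_yield")
        preds = {
            c[len("pred_") :]: float(r[c])
            for c in pred_cols
            if not pd.isna(r[c])
        }
        records.append(
            YieldRecord(
                region_id=str(r["region"]),
                year=int(r["year"]),
                sum_npp=float(r["sum_npp"]),
                observed_yield=None if obs is None or pd.isna(obs) else float(obs),
                predictions=preds,
            )
        )
    return records


def write_yields_csv(path, records: Sequence[YieldRecord]) -> None:
    models = sorted({m for r in records for m in r.predictions})
    pd.DataFrame(
        [
            {
                "region": r.region_id,
                "year": r.year,
                "sum_npp": r.sum_npp,
                "observed_yield": "" if r.observed_yield is None else r.observed_yield,
                **{f"pred_{m}": r.predictions.get(m, float("nan")) for m in models},
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def write_scores(path_prefix, scores: Sequence[ModelScores]) -> tuple[Path, Path]:
    """Write the comparison table as <prefix>.csv and <prefix>.json."""
    from .evaluation import scores_to_frame

    prefix = Path(path_prefix)
    csv_path = prefix.with_suffix(".csv")
    json_path = prefix.with_suffix(".json")
    frame = scores_to_frame(scores)
    frame.to_csv(csv_path, index=False)
    json_path.write_text(json.dumps(frame.to_dict("records"), indent=2))
    return csv_path, json_path


def write_simulation(config, out_dir) -> dict[str, Path]:
    """Materialise a synthetic dataset: meteorology, composites, yields,
    features and a JSON sidecar echoing the full config (incl. the truth)."""
    from .features import build_feature_table
    from .simulate import generate_season, generate_yield_dataset, region_ids

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seasons = [
        generate_season(config, rid, year)
        for rid in region_ids(config)
        for year in config.years
    ]
    records = generate_yield_dataset(config, seasons=seasons)
    features = build_feature_table(seasons, [r.observed_yield for r in records])

    paths = {
        "meteorology": out / "meteorology.csv",
        "composites": out / "composites.csv",
        "yields": out / "yields.csv",
        "features": out / "features.csv",
        "config": out / "sim_config.json",
    }
    write_meteorology_csv(
        paths["meteorology"],
        {(s.region_id, s.year): s.meteo for s in seasons},
    )
    write_composites_csv(paths["composites"], seasons)
    write_yields_csv(paths["yields"], records)
    write_features_csv(paths["features"], features)
    paths["config"].write_text(json.dumps(config.to_dict(), indent=2))
    return paths
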