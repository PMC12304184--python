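"""Environmental stress scalars of the light-use-efficiency model.

Realised light-use efficiency is the biome maximum εmax down-scaled by three
multiplicative scalars in [0, 1]:

    ε = εmax · Ts · Ws · Ps

* ``Ts`` — temperature stress, a quadratic-ratio response of the composite
  mean temperature T between photosynthetic limits Tmin/Tmax with optimum
  Topt (30 °C for corn and soybean).
* ``Ws`` — water stress from the land surface water index
  LSWI = (NIR − SWIR)/(NIR + SWIR) relative to its growing-season maximum.
* ``Ps`` — phenology-phase scalar: 1 during leaf growth, (1 + LSWI)/2 during
  grain ripening.

Two Ws conventions are implemented.  The ``as_printed`` form
(1 − LSWI)/(1 + LSWImax) approaches 1 under drought yet multiplies ε, which
contradicts the standard vegetation-photosynthesis-model (VPM) scalar
(1 + LSWI)/(1 + LSWImax); both are exposed via ``ws_formula`` and clamped to
[0, 1], with ``as_printed`` the default.  See docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

from .errors import DomainError, InvalidConfigError, InvalidInputError
from .types import CompositeObservation, SeasonSeries, StressFactors, doy_of

__all__ = [
    "CropStressParams",
    "compute_lswi",
    "water_stress",
    "seasonal_lswi_max",
    "temperature_stress",
    "vegetation_growth_scalar",
    "light_use_efficiency",
    "season_stress_factors",
]

#: Maximum light-use efficiency for corn/soybean cropland, gC MJ⁻¹.
EPS_MAX_DEFAULT = 0.34
#: Optimum photosynthesis temperature for corn and soybean, °C.
T_OPT_DEFAULT = 30.0
#: Default phenology-phase transition: Aug 1 (DOY 213 in non-leap years).
PHASE_TRANSITION_DOY_DEFAULT = 213


@dataclass(frozen=True)
class CropStressParams:
    """Parameters of the stress-scalar model.

    ``temp_limit_mode`` chooses where Eq. Ts takes its Tmin/Tmax from:
    ``daily_observed`` uses the composite-period means of the observed daily
    minima/maxima; ``crop_constants`` uses the fixed photosynthetic limits
    ``t_min_const``/``t_max_const`` of the VPM lineage.
    """

    eps_max: float = EPS_MAX_DEFAULT
    t_opt: float = T_OPT_DEFAULT
    temp_limit_mode: Literal["daily_observed", "crop_constants"] = "daily_observed"
    t_min_const: float = 10.0
    t_max_const: float = 40.0
    ws_formula: Literal["as_printed", "vpm_standard"] = "as_printed"
    phase_transition_doy: int = PHASE_TRANSITION_DOY_DEFAULT

    def __post_init__(self) -> None:
        if self.eps_max <= 0:
            raise InvalidConfigError(f"eps_max={self.eps_max} must be > 0")
        if self.temp_limit_mode not in ("daily_observed", "crop_constants"):
            raise InvalidConfigError(f"unknown temp_limit_mode {self.temp_limit_mode!r}")
        if self.ws_formula not in ("as_printed", "vpm_standard"):
            raise InvalidConfigError(f"unknown ws_formula {self.ws_formula!r}")
        if self.temp_limit_mode == "crop_constants" and not (
            self.t_min_const < self.t_opt < self.t_max_const
        ):
            raise InvalidConfigError(
                "crop_constants mode requires t_min_const < t_opt < t_max_const, "
                f"got {self.t_min_const} / {self.t_opt} / {self.t_max_const}"
            )
        if not 1 <= self.phase_transition_doy <= 366:
            raise InvalidConfigError("phase_transition_doy outside [1, 366]")


def _clamp01(x: float) -> float:
    return min(1.0, max(0.0, x))


def compute_lswi(nir: float, swir: float, *, composite_index: int | None = None) -> float:
    """Land surface water index (NIR − SWIR)/(NIR + SWIR).

    Bounded in [−1, 1] for non-negative reflectances; higher values indicate
    more canopy/soil moisture.
    """
    if nir < 0 or swir < 0:
        raise InvalidInputError(f"negative reflectance (nir={nir}, swir={swir})")
    denom = nir + swir
    if denom == 0:
        where = "" if composite_index is None else f" at composite {composite_index}"
        raise DomainError(f"LSWI undefined: nir + swir = 0{where}")
    return (nir - swir) / denom


def water_stress(
    lswi: float,
    lswi_max: float,
    formula: Literal["as_printed", "vpm_standard"] = "as_printed",
) -> float:
    """Water-stress scalar from LSWI and its seasonal maximum, clamped to [0, 1].

    ``as_printed`` returns (1 − LSWI)/(1 + LSWImax), which grows with drought;
    ``vpm_standard`` returns (1 + LSWI)/(1 + LSWImax), which grows with
    moisture.  Both raw ratios can exceed [0, 1] and are clamped.
    """
    if not -1.0 <= lswi <= 1.0:
        raise InvalidInputError(f"lswi={lswi} outside [-1, 1]")
    if not -1.0 <= lswi_max <= 1.0:
        raise InvalidInputError(f"lswi_max={lswi_max} outside [-1, 1]")
    denom = 1.0 + lswi_max
    if denom <= 0:
        raise DomainError(f"water stress undefined: 1 + lswi_max = {denom} <= 0")
    if formula == "as_printed":
        raw = (1.0 - lswi) / denom
    elif formula == "vpm_standard":
        raw = (1.0 + lswi) / denom
    else:
        raise InvalidConfigError(f"unknown ws_formula {formula!r}")
    return _clamp01(raw)


def seasonal_lswi_max(composites: Sequence[CompositeObservation]) -> float:
    """Maximum LSWI over a season's composites (the LSWImax of Ws)."""
    if not composites:
        raise InvalidInputError("seasonal_lswi_max of an empty composite list")
    return max(
        compute_lswi(c.nir, c.swir, composite_index=i) for i, c in enumerate(composites)
    )


def temperature_stress(t_mean: float, t_min: float, t_max: float, t_opt: float) -> float:
    """Temperature-stress scalar.

    Ts = (T−Tmin)(T−Tmax) / [(T−Tmin)(T−Tmax) − (T−Topt)²], clamped to
    [0, 1]; outside the viable range [Tmin, Tmax] photosynthesis is shut down
    and Ts = 0.  Equals 1 at T = Topt.
    """
    if t_min >= t_max:
        raise InvalidInputError(f"t_min={t_min} must be < t_max={t_max}")
    if t_mean <= t_min or t_mean >= t_max:
        return 0.0
    num = (t_mean - t_min) * (t_mean - t_max)
    denom = num - (t_mean - t_opt) ** 2
    if denom == 0:
        raise DomainError(
            "temperature stress undefined: zero denominator at "
            f"T={t_mean}, Tmin={t_min}, Tmax={t_max}, Topt={t_opt}"
        )
    return _clamp01(num / denom)


def vegetation_growth_scalar(
    phase: Literal["leaf_growth", "grain_ripening"], lswi: float
) -> float:
    """Phenology-phase scalar Ps: 1 in leaf growth, (1 + LSWI)/2 in ripening."""
    if not -1.0 <= lswi <= 1.0:
        raise InvalidInputError(f"lswi={lswi} outside [-1, 1]")
    if phase == "leaf_growth":
        return 1.0
    if phase == "grain_ripening":
        return (1.0 + lswi) / 2.0
    raise InvalidConfigError(f"unknown phase {phase!r}")


def light_use_efficiency(
    ts: float, ws: float, ps: float, params: CropStressParams | None = None
) -> float:
    """Realised light-use efficiency ε = εmax · Ts · Ws · Ps (gC MJ⁻¹)."""
    params = params or CropStressParams()
    for name, value in (("ts", ts), ("ws", ws), ("ps", ps)):
        if not 0.0 <= value <= 1.0:
            raise InvalidInputError(f"{name}={value} outside [0, 1]")
    return params.eps_max * ts * ws * ps


def _composite_phase(comp: CompositeObservation, params: CropStressParams) -> str:
    return (
        "leaf_growth"
        if comp.start_doy < params.phase_transition_doy
        else "grain_ripening"
    )


def season_stress_factors(
    season: SeasonSeries, params: CropStressParams | None = None
) -> list[StressFactors]:
    """Per-composite LSWI, Ws, Ts, Ps and ε for one region-year.

    Ts uses the composite-period mean of the daily mean temperature; Tmin and
    Tmax come from the composite-period means of daily minima/maxima
    (``daily_observed``) or from the crop constants.  Ws is relative to this
    season's LSWI maximum.  The phase switches from leaf growth to grain
    ripening for composites starting at or after ``phase_transition_doy``.
    """
    params = params or CropStressParams()
    if not season.composites:
        raise InvalidInputError(f"{season.region_id}/{season.year}: no composites")
    lswi_max = seasonal_lswi_max(season.composites)

    out: list[StressFactors] = []
    for i, comp in enumerate(season.composites):
        try:
            lswi = compute_lswi(comp.nir, comp.swir, composite_index=i)
            ws = water_stress(lswi, lswi_max, params.ws_formula)
            days = season.composite_meteo(i)
            t_mean = sum(d.mean_temperature for d in days) / len(days)
            if params.temp_limit_mode == "daily_observed":
                t_min = sum(d.tmin for d in days) / len(days)
                t_max = sum(d.tmax for d in days) / len(days)
            else:
                t_min, t_max = params.t_min_const, params.t_max_const
            ts = temperature_stress(t_mean, t_min, t_max, params.t_opt)
            ps = vegetation_growth_scalar(_composite_phase(comp, params), lswi)
            eps = light_use_efficiency(ts, ws, ps, params)
        except InvalidInputError as exc:
            raise type(exc)(
                f"{season.region_id}/{season.year} composite {i}: {exc}"
            ) from exc
        out.append(
            StressFactors(composite_index=i, lswi=lswi, ws=ws, ts=ts, ps=ps, epsilon=eps)
        )
    return out
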