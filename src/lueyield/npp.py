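"""Seasonal NPP accumulation and the NPP → yield regression.

Net primary productivity accumulates over the growing season's composites as

    ΣNPP = Σᵢ PARᵢ · fAPARᵢ · εᵢ · Δtᵢ      [gC m⁻²]

with PAR the mean daily photosynthetically active radiation of composite i
(MJ m⁻² d⁻¹), Δt its length in days, and ε the realised light-use efficiency
from :mod:`lueyield.stress`.  Yield follows the linear model

    Yield = a · ΣNPP + b                    [ton ha⁻¹]

with published constants a = 0.12, b = 0.739 for corn and a = 0.073,
b = 1.298 for soybean.  The scale linking gC m⁻² to those constants is not
stated by their source; ``npp_scale`` multiplies ΣNPP before the regression
and defaults to 1 (see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateDataError, InvalidConfigError, InvalidInputError
from .stress import CropStressParams, season_stress_factors
from .types import CompositeObservation, SeasonSeries, StressFactors, YieldRecord

__all__ = [
    "RegressionConstants",
    "accumulate_npp",
    "yield_from_npp",
    "calibrate_yield_regression",
    "run_semi_physical",
    "SEMI_PHYSICAL_MODEL_NAME",
]

SEMI_PHYSICAL_MODEL_NAME = "semi_physical"

#: Published NPP→yield regression constants (ton ha⁻¹ intercept).
DEFAULT_CONSTANTS: dict[str, tuple[float, float]] = {
    "corn": (0.12, 0.739),
    "soybean": (0.073, 1.298),
}


@dataclass(frozen=True)
class RegressionConstants:
    """Slope/intercept of the linear NPP → yield model for one crop."""

    crop: str
    a: float
    b: float
    #: 1-sigma uncertainties when the constants come from a fit, else None.
    a_se: float | None = None
    b_se: float | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.a) and math.isfinite(self.b)):
            raise InvalidConfigError("regression constants must be finite")

    @classmethod
    def for_crop(cls, crop: str) -> "RegressionConstants":
        """The published constants for ``corn`` or ``soybean``."""
        try:
            a, b = DEFAULT_CONSTANTS[crop]
        except KeyError:
            raise InvalidConfigError(
                f"unknown crop {crop!r}; expected one of {sorted(DEFAULT_CONSTANTS)}"
            ) from None
        return cls(crop=crop, a=a, b=b)


def accumulate_npp(
    composites: Sequence[CompositeObservation],
    stress: Sequence[StressFactors],
) -> float:
    """Seasonal ΣNPP (gC m⁻²) from index-aligned composites and stress factors."""
    if len(composites) != len(stress):
        raise InvalidInputError(
            f"{len(composites)} composites but {len(stress)} stress factors"
        )
    return float(
        sum(
            c.par_daily_mean * c.n_days * c.fapar * s.epsilon
            for c, s in zip(composites, stress)
        )
    )


def yield_from_npp(sum_npp: float, constants: RegressionConstants) -> float:
    """Yield (ton ha⁻¹) from seasonal ΣNPP via the linear model a·ΣNPP + b."""
    if sum_npp < 0:
        raise InvalidInputError(f"sum_npp={sum_npp} < 0")
    return constants.a * sum_npp + constants.b


def calibrate_yield_regression(
    pairs: Sequence[tuple[float, float]], crop: str = "corn"
) -> RegressionConstants:
    """Ordinary-least-squares fit of observed yield on ΣNPP.

    Returns the fitted (a, b) with their standard errors.  Requires at least
    two pairs with distinct ΣNPP values.
    """
    if len(pairs) < 2:
        raise DegenerateDataError("need >= 2 (sum_npp, yield) pairs to calibrate")
    x = np.asarray([p[0] for p in pairs], dtype=float)
    y = np.asarray([p[1] for p in pairs], dtype=float)
    if np.unique(x).size < 2:
        raise DegenerateDataError("all sum_npp values identical; slope unidentifiable")

    import statsmodels.api as sm

    res = sm.OLS(y, sm.add_constant(x)).fit()
    b, a = res.params
    if len(pairs) > 2:
        b_se, a_se = res.bse
    else:  # exact two-point fit: no residual dof
        a_se = b_se = None
    return RegressionConstants(
        crop=crop, a=float(a), b=float(b),
        a_se=None if a_se is None else float(a_se),
        b_se=None if b_se is None else float(b_se),
    )


def run_semi_physical(
    seasons: Sequence[SeasonSeries],
    params: CropStressParams | None = None,
    constants: RegressionConstants | None = None,
    *,
    npp_scale: float = 1.0,
    observed: Sequence[float | None] | None = None,
) -> list[YieldRecord]:
    """Stress factors → ΣNPP → predicted yield for each season.

    Predictions are tagged under the model name ``semi_physical``.  When
    ``observed`` yields are supplied (index-aligned with ``seasons``) they are
    carried onto the records for later scoring.
    """
    params = params or CropStressParams()
    constants = constants or RegressionConstants.for_crop("corn")
    if observed is not None and len(observed) != len(seasons):
        raise InvalidInputError("observed yields not index-aligned with seasons")

    records: list[YieldRecord] = []
    for i, season in enumerate(seasons):
        stress = season_stress_factors(season, params)
        sum_npp = accumulate_npp(season.composites, stress)
        predicted = yield_from_npp(sum_npp * npp_scale, constants)
        records.append(
            YieldRecord(
                region_id=season.region_id,
                year=season.year,
                sum_npp=sum_npp,
                observed_yield=None if observed is None else observed[i],
                predictions={SEMI_PHYSICAL_MODEL_NAME: predicted},
            )
        )
    return records
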