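"""Model/Results objects over the pipeline, in the statsmodels idiom.

:class:`SemiPhysicalYieldModel` wraps the stress → NPP → regression chain:
construct it from seasons and observed yields, call :meth:`fit` to calibrate
the NPP→yield line by OLS (or :meth:`predict` to apply published constants),
and read estimates, standard errors and skill metrics off the results.

:class:`ANNYieldModel` wraps the neural-network protocol: 70/15/15 split,
z-score standardisation fitted on the training rows, seeded Rprop training
with validation early stopping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .ann import (
    ANN_MODEL_NAME,
    FeatureScaler,
    MLPModel,
    MLPSpec,
    predict_yield,
    split_dataset,
    standardize_features,
    train_mlp,
)
from .errors import InvalidInputError
from .evaluation import comparison_table, pearson_r, r_squared, rmse
from .npp import (
    SEMI_PHYSICAL_MODEL_NAME,
    RegressionConstants,
    accumulate_npp,
    calibrate_yield_regression,
    run_semi_physical,
    yield_from_npp,
)
from .stress import CropStressParams, season_stress_factors
from .types import FeatureVector, SeasonSeries, SplitAssignment, YieldRecord

__all__ = [
    "SemiPhysicalYieldModel",
    "SemiPhysicalResults",
    "ANNYieldModel",
    "ANNResults",
]


class SemiPhysicalYieldModel:
    """Light-use-efficiency yield model for one crop over many region-years.

    Parameters
    ----------
    seasons : sequence of SeasonSeries
        Region-year inputs (composites required; meteorology required for
        temperature stress).
    observed_yield : sequence of float, optional
        Observed yields (ton/ha), index-aligned with ``seasons``; required
        for :meth:`fit`.
    crop : {"corn", "soybean"}
    stress_params : CropStressParams, optional
    npp_scale : float
        Multiplier applied to ΣNPP before the yield regression.
    """

    def __init__(
        self,
        seasons: Sequence[SeasonSeries],
        observed_yield: Sequence[float] | None = None,
        *,
        crop: str = "corn",
        stress_params: CropStressParams | None = None,
        npp_scale: float = 1.0,
    ) -> None:
        if not seasons:
            raise InvalidInputError("no seasons supplied")
        if observed_yield is not None and len(observed_yield) != len(seasons):
            raise InvalidInputError("observed_yield not aligned with seasons")
        self.seasons = list(seasons)
        self.observed_yield = None if observed_yield is None else list(observed_yield)
        self.crop = crop
        self.stress_params = stress_params or CropStressParams()
        self.npp_scale = npp_scale
        self._sum_npp: np.ndarray | None = None

    @classmethod
    def from_records(
        cls, seasons: Sequence[SeasonSeries], records: Sequence[YieldRecord], **kwargs
    ) -> "SemiPhysicalYieldModel":
        by_key = {(r.region_id, r.year): r for r in records}
        obs = [by_key[(s.region_id, s.year)].observed_yield for s in seasons]
        return cls(seasons, obs, **kwargs)

    @property
    def sum_npp(self) -> np.ndarray:
        """Seasonal ΣNPP (gC m⁻²) per region-year, computed once."""
        if self._sum_npp is None:
            values = []
            for season in self.seasons:
                stress = season_stress_factors(season, self.stress_params)
                values.append(accumulate_npp(season.composites, stress))
            self._sum_npp = np.asarray(values)
        return self._sum_npp

    def fit(self) -> "SemiPhysicalResults":
        """Calibrate the NPP→yield line by OLS against the observed yields."""
        if self.observed_yield is None or any(
            y is None for y in self.observed_yield
        ):
            raise InvalidInputError("fit() requires observed yields for every season")
        x = self.sum_npp * self.npp_scale
        constants = calibrate_yield_regression(
            list(zip(x, self.observed_yield)), crop=self.crop
        )
        return SemiPhysicalResults(model=self, constants=constants, calibrated=True)

    def predict(
        self, constants: RegressionConstants | None = None
    ) -> "SemiPhysicalResults":
        """Apply fixed (default: published) constants without fitting."""
        constants = constants or RegressionConstants.for_crop(self.crop)
        return SemiPhysicalResults(model=self, constants=constants, calibrated=False)


@dataclass
class SemiPhysicalResults:
    """Estimates and skill of a (possibly calibrated) semi-physical model."""

    model: SemiPhysicalYieldModel
    constants: RegressionConstants
    calibrated: bool

    @property
    def params(self) -> tuple[float, float]:
        """(a, b): slope (ton/ha per NPP unit) and intercept (ton/ha)."""
        return (self.constants.a, self.constants.b)

    @property
    def bse(self) -> tuple[float | None, float | None]:
        """Standard errors of (a, b); None when not calibrated here."""
        return (self.constants.a_se, self.constants.b_se)

    @property
    def fittedvalues(self) -> np.ndarray:
        x = self.model.sum_npp * self.model.npp_scale
        return self.constants.a * x + self.constants.b

    @property
    def records(self) -> list[YieldRecord]:
        return run_semi_physical(
            self.model.seasons,
            self.model.stress_params,
            self.constants,
            npp_scale=self.model.npp_scale,
            observed=self.model.observed_yield,
        )

    def _pair(self):
        if self.model.observed_yield is None:
            raise InvalidInputError("no observed yields to score against")
        return np.asarray(self.model.observed_yield, dtype=float), self.fittedvalues

    @property
    def rsquared(self) -> float:
        obs, pred = self._pair()
        return r_squared(obs, pred)

    @property
    def rmse(self) -> float:
        obs, pred = self._pair()
        return rmse(obs, pred)

    @property
    def pearson_r(self) -> float:
        obs, pred = self._pair()
        return pearson_r(obs, pred)

    @property
    def nobs(self) -> int:
        return len(self.model.seasons)

    def scores(self):
        """Comparison-table rows (overall split) for this model."""
        return comparison_table(self.records, self.model.crop)

    def summary(self) -> str:
        a, b = self.params
        a_se, b_se = self.bse
        lines = [
            "Semi-physical LUE yield model",
            "=" * 46,
            f"crop:            {self.model.crop}",
            f"region-years:    {self.nobs}",
            f"constants:       {'calibrated (OLS)' if self.calibrated else 'fixed'}",
            f"slope a:         {a:.6f}"
            + (f"  (SE {a_se:.6f})" if a_se is not None else ""),
            f"intercept b:     {b:.6f} ton/ha"
            + (f"  (SE {b_se:.6f})" if b_se is not None else ""),
            f"npp_scale:       {self.model.npp_scale}",
        ]
        if self.model.observed_yield is not None:
            lines += [
                f"R^2:             {self.rsquared:.4f}",
                f"RMSE:            {self.rmse:.4f} ton/ha",
                f"Pearson r:       {self.pearson_r:.4f}",
            ]
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Observed vs predicted yield scatter with the 1:1 line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        obs, pred = self._pair()
        ax.scatter(obs, pred, s=18, alpha=0.7)
        lo, hi = min(obs.min(), pred.min()), max(obs.max(), pred.max())
        ax.plot([lo, hi], [lo, hi], "k--", lw=1)
        ax.set_xlabel("observed yield (ton/ha)")
        ax.set_ylabel("predicted yield (ton/ha)")
        ax.set_title(f"semi-physical model, {self.model.crop}")
        return ax


class ANNYieldModel:
    """The 9–10–1 neural-network yield baseline with its full protocol."""

    def __init__(
        self,
        rows: Sequence[FeatureVector],
        spec: MLPSpec | None = None,
        *,
        split_seed: int = 0,
    ) -> None:
        if any(r.target is None for r in rows):
            raise InvalidInputError("every feature row needs an observed yield")
        self.rows = list(rows)
        self.spec = spec or MLPSpec()
        self.split_seed = split_seed

    def fit(self) -> "ANNResults":
        split = split_dataset(len(self.rows), self.split_seed)
        train_rows = [self.rows[i] for i in split.train]
        std_train, scaler = standardize_features(train_rows, self.spec.scaling)
        std_val = scaler.transform_rows([self.rows[i] for i in split.validation])
        net = train_mlp(self.spec, std_train, std_val)
        return ANNResults(model=self, net=net, scaler=scaler, split=split)


@dataclass
class ANNResults:
    """A trained network plus its split, scaler and training history."""

    model: ANNYieldModel
    net: MLPModel
    scaler: FeatureScaler
    split: SplitAssignment

    def predict(self, rows: Sequence[FeatureVector] | None = None) -> np.ndarray:
        rows = self.model.rows if rows is None else rows
        return predict_yield(self.net, self.scaler.transform_rows(rows))

    def _subset_scores(self, indices) -> dict[str, float]:
        rows = [self.model.rows[i] for i in indices]
        obs = np.asarray([r.target for r in rows], dtype=float)
        pred = self.predict(rows)
        return {
            "r2": r_squared(obs, pred),
            "rmse": rmse(obs, pred),
            "pearson_r": pearson_r(obs, pred),
            "n": len(rows),
        }

    @property
    def test_rsquared(self) -> float:
        return self._subset_scores(self.split.test)["r2"]

    def history_frame(self):
        """Per-epoch train/validation MSE as a DataFrame (performance plot data)."""
        import pandas as pd

        return pd.DataFrame(
            self.net.history, columns=["epoch", "train_mse", "validation_mse"]
        )

    def records(self, crop: str | None = None) -> list[YieldRecord]:
        preds = self.predict()
        return [
            YieldRecord(
                region_id=r.region_id,
                year=r.year,
                sum_npp=0.0,
                observed_yield=r.target,
                predictions={ANN_MODEL_NAME: float(p)},
            )
            for r, p in zip(self.model.rows, preds)
        ]

    def scores(self, crop: str):
        return comparison_table(self.records(), crop, self.split)

    def summary(self) -> str:
        parts = {
            name: self._subset_scores(idx)
            for name, idx in (
                ("train", self.split.train),
                ("validation", self.split.validation),
                ("test", self.split.test),
            )
        }
        lines = [
            "Neural-network yield baseline "
            f"({self.net.spec.n_input}-{self.net.spec.n_hidden}-{self.net.spec.n_output})",
            "=" * 46,
            f"rows: {len(self.model.rows)}  split seed: {self.split.seed}  "
            f"net seed: {self.net.spec.seed}",
            f"best epoch: {self.net.best_epoch} of {len(self.net.history)} run",
        ]
        for name, sc in parts.items():
            lines.append(
                f"{name:<11} n={sc['n']:<4} R^2={sc['r2']:.4f}  "
                f"RMSE={sc['rmse']:.4f}  r={sc['pearson_r']:.4f}"
            )
        return "\n".join(lines)

    def plot_history(self, ax=None):
        """Train/validation MSE per epoch (the performance plot)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        frame = self.history_frame()
        ax.plot(frame["epoch"], frame["train_mse"], label="train")
        ax.plot(frame["epoch"], frame["validation_mse"], label="validation")
        ax.axvline(self.net.best_epoch, color="k", ls=":", lw=1, label="best epoch")
        ax.set_xlabel("epoch")
        ax.set_ylabel("MSE (ton/ha)^2")
        ax.set_yscale("log")
        ax.legend()
        return ax
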