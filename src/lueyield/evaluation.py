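"""Model-comparison metrics: RMSE, coefficient of determination, Pearson r.

R² here is the coefficient of determination 1 − SS_res/SS_tot about the
observed mean — it can be negative for predictions worse than the mean and
only coincides with squared correlation for calibrated (OLS-fitted)
predictions.  Pearson r is reported alongside.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .errors import DegenerateDataError, InvalidInputError
from .types import ModelScores, SplitAssignment, YieldRecord

__all__ = ["rmse", "r_squared", "pearson_r", "comparison_table", "scores_to_frame"]

_SPLIT_ORDER = {"calibration": 0, "validation": 1, "test": 2, "overall": 3}


def _as_pair(observed: Sequence[float], predicted: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.size == 0:
        raise InvalidInputError("empty observation vector")
    if obs.shape != pred.shape:
        raise InvalidInputError(
            f"length mismatch: {obs.size} observed vs {pred.size} predicted"
        )
    return obs, pred


def rmse(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Root-mean-squared error, in the units of the observations (ton ha⁻¹)."""
    obs, pred = _as_pair(observed, predicted)
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def r_squared(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Coefficient of determination 1 − SS_res/SS_tot about the observed mean."""
    obs, pred = _as_pair(observed, predicted)
    if obs.size < 2:
        raise InvalidInputError("r_squared needs >= 2 observations")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise DegenerateDataError("observed values have zero variance")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def pearson_r(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Pearson correlation; 0 by convention when predictions are constant."""
    obs, pred = _as_pair(observed, predicted)
    if obs.size < 2:
        raise InvalidInputError("pearson_r needs >= 2 observations")
    if np.std(obs) == 0 or np.std(pred) == 0:
        return 0.0
    return float(np.corrcoef(obs, pred)[0, 1])


def _score(model: str, crop: str, split: str, obs, pred) -> ModelScores:
    return ModelScores(
        model=model,
        crop=crop,
        split=split,
        r2=r_squared(obs, pred),
        rmse=rmse(obs, pred),
        pearson_r=pearson_r(obs, pred),
        n=len(obs),
    )


def comparison_table(
    records: Sequence[YieldRecord],
    crop: str,
    splits: SplitAssignment | None = None,
    *,
    split_models: Sequence[str] | None = None,
) -> list[ModelScores]:
    """Score every model found on ``records`` against the observed yields.

    Emits one row per (model, crop, split).  The ``overall`` split is always
    present; when a :class:`SplitAssignment` is given, per-split rows are
    added for the models listed in ``split_models`` (default: every model
    except ``semi_physical``, which involves no fitting split).  Rows are
    ordered by (model, crop, split).
    """
    if not records:
        raise InvalidInputError("no records to score")
    if any(r.observed_yield is None for r in records):
        raise InvalidInputError("every record must carry an observed yield")
    models = sorted({m for r in records for m in r.predictions})
    if not models:
        raise InvalidInputError("records carry no model predictions")
    if splits is not None and splits.n != len(records):
        raise InvalidInputError("split assignment does not match record count")

    # canonical record order so scoring is permutation-invariant bit-for-bit
    order = sorted(range(len(records)), key=lambda i: (records[i].region_id, records[i].year))
    rows: list[ModelScores] = []
    for model in models:
        idx = [i for i in order if model in records[i].predictions]
        obs = [records[i].observed_yield for i in idx]
        pred = [records[i].predictions[model] for i in idx]
        rows.append(_score(model, crop, "overall", obs, pred))
        wants_splits = splits is not None and (
            model in split_models
            if split_models is not None
            else model != "semi_physical"
        )
        if wants_splits:
            for name, members in (
                ("calibration", splits.train),
                ("validation", splits.validation),
                ("test", splits.test),
            ):
                sub = [i for i in idx if i in set(members)]
                if len(sub) >= 2:
                    rows.append(
                        _score(
                            model,
                            crop,
                            name,
                            [records[i].observed_yield for i in sub],
                            [records[i].predictions[model] for i in sub],
                        )
                    )
    rows.sort(key=lambda s: (s.model, s.crop, _SPLIT_ORDER[s.split]))
    return rows


def scores_to_frame(scores: Sequence[ModelScores]):
    """Comparison table as a pandas DataFrame (model, crop, split, r2, ...)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "model": s.model,
                "crop": s.crop,
                "split": s.split,
                "r2": s.r2,
                "rmse": s.rmse,
                "pearson_r": s.pearson_r,
                "n": s.n,
            }
            for s in scores
        ]
    )
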