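"""Validated pipeline configuration (JSON/YAML file → typed object).

Unknown keys are rejected outright so a typo cannot silently fall back to a
default.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import pydantic

from .ann import MLPSpec
from .errors import InvalidConfigError
from .npp import RegressionConstants
from .stress import CropStressParams


class StressConfig(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")

    eps_max: float = 0.34
    t_opt: float = 30.0
    temp_limit_mode: Literal["daily_observed", "crop_constants"] = "daily_observed"
    t_min_const: float = 10.0
    t_max_const: float = 40.0
    ws_formula: Literal["as_printed", "vpm_standard"] = "as_printed"
    phase_transition_doy: int = 213

    def to_params(self) -> CropStressParams:
        return CropStressParams(**self.model_dump())


class AnnConfig(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")

    n_hidden: int = 10
    n_hidden_layers: int = 1
    max_epochs: int = 2000
    patience: int = 100
    scaling: Literal["zscore", "minmax"] = "zscore"

    def to_spec(self, seed: int) -> MLPSpec:
        return MLPSpec(
            n_hidden=self.n_hidden,
            n_hidden_layers=self.n_hidden_layers,
            max_epochs=self.max_epochs,
            patience=self.patience,
            scaling=self.scaling,
            seed=seed,
        )


class PipelineConfig(pydantic.BaseModel):
    """Everything the CLI subcommands need beyond their file arguments."""

    model_config = pydantic.ConfigDict(extra="forbid")

    crop: Literal["corn", "soybean"] = "corn"
    latitude_deg: float = 40.0  # central Illinois
    stress: StressConfig = StressConfig()
    regression: Literal["calibrate"] | tuple[float, float] = "calibrate"
    npp_scale: float = 1.0
    ann: AnnConfig = AnnConfig()
    split_seed: int = 0

    def regression_constants(self) -> Optional[RegressionConstants]:
        """Fixed constants, or None when calibration is requested."""
        if self.regression == "calibrate":
            return None
        a, b = self.regression
        return RegressionConstants(crop=self.crop, a=a, b=b)


def load_pipeline_config(path) -> PipelineConfig:
    """Read and validate a JSON or YAML pipeline configuration file."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    try:
        return PipelineConfig.model_validate(data or {})
    except pydantic.ValidationError as exc:
        raise InvalidConfigError(str(exc)) from exc
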