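"""Run configuration: a strict, YAML-round-trippable parameter schema.

Every classifier threshold shipped here is a declared default, not a
published constant, so the resolved configuration is echoed into every
result document.  Unknown keys are rejected.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .core import ClassifierParams

__all__ = ["ClassifierConfig", "DecisionConfig", "EvaluationConfig", "RunConfig"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ClassifierConfig(_Strict):
    window_n: int = Field(default=32, ge=8)
    w_v: float = Field(default=0.5, ge=0)
    w_r: float = Field(default=0.5, ge=0)
    theta_af: float = Field(default=0.55, gt=0, le=1)
    theta_sr: float = Field(default=0.25, ge=0, lt=1)
    v_scale: float = Field(default=0.1, gt=0)
    delta_ms: float = Field(default=40.0, ge=0)

    @model_validator(mode="after")
    def _check(self) -> "ClassifierConfig":
        if abs(self.w_v + self.w_r - 1.0) > 1e-9:
            raise ValueError("w_v + w_r must equal 1")
        if not self.theta_sr < self.theta_af:
            raise ValueError("theta_sr must be < theta_af")
        return self

    def to_params(self) -> ClassifierParams:
        return ClassifierParams(**self.model_dump())


class DecisionConfig(_Strict):
    min_af_fraction: float = Field(default=0.90, gt=0, le=1)
    weighting: str = Field(default="duration", pattern="^(duration|count)$")


class EvaluationConfig(_Strict):
    ci_method: str = Field(default="exact", pattern="^(exact|wilson)$")
    alpha: float = Field(default=0.05, gt=0, lt=1)


class RunConfig(_Strict):
    classifier: ClassifierConfig = ClassifierConfig()
    decision: DecisionConfig = DecisionConfig()
    evaluation: EvaluationConfig = EvaluationConfig()
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=True)
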