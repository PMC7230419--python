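"""Run configuration: a YAML mapping with a validated schema.

A config file may override any model parameter, define named scenarios,
supply population anchors, and set report options. Absent keys fall
back to the national baseline defaults; unknown keys are rejected so a
typo cannot silently change a run.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .demography import PopulationProjection
from .model import ModelParameters, Schedule
from .scenarios import Scenario
from .synthetic import generate_population_anchors

__all__ = ["RunConfig", "load_config", "save_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ParameterOverrides(_Strict):
    """Optional overrides of the baseline model parameters."""

    enrollment: Optional[float] = Field(None, ge=0)
    study_duration: Optional[int] = Field(None, ge=1)
    student_dropout_frac: Optional[float] = Field(None, ge=0, le=1)
    immigrants: Optional[float] = Field(None, ge=0)
    waiting_emigration_rate: Optional[float] = Field(None, ge=0, le=1)
    waiting_other_outflow: Optional[float] = Field(None, ge=0)
    st_duration: Optional[int] = Field(None, ge=1)
    st_dropout_rate: Optional[float] = Field(None, ge=0, le=1)
    specialist_attrition_rate: Optional[float] = Field(None, ge=0, le=1)
    specialist_entry_age: Optional[int] = Field(None, ge=18)
    gp_retirement_horizon: Optional[int] = Field(None, ge=1)
    outside_care_horizon: Optional[int] = Field(None, ge=1)


class ScenarioConfig(_Strict):
    """One named scenario: schedules as {year: value} breakpoints."""

    enrollment: Dict[int, float] = Field(default_factory=lambda: {2017: 590.0})
    licenses: Dict[int, float] = Field(default_factory=lambda: {2017: 450.0})
    start_year: int = 2017
    end_year: int = 2041

    @field_validator("enrollment", "licenses")
    @classmethod
    def _non_negative(cls, v: Dict[int, float]) -> Dict[int, float]:
        if not v:
            raise ValueError("schedule needs at least one breakpoint")
        for year, value in v.items():
            if value < 0:
                raise ValueError(f"negative schedule value {value} in year {year}")
        return v

    def to_scenario(self, name: str) -> Scenario:
        return Scenario(
            name=name,
            enrollment_schedule=Schedule(self.enrollment),
            license_schedule=Schedule(self.licenses),
            start_year=self.start_year,
            end_year=self.end_year,
        )


class RunConfig(_Strict):
    """Full run configuration with baseline defaults filled in."""

    parameters: ParameterOverrides = Field(default_factory=ParameterOverrides)
    scenarios: Dict[str, ScenarioConfig] = Field(
        default_factory=lambda: {
            "scenario-1": ScenarioConfig(licenses={2017: 450.0}),
            "scenario-2": ScenarioConfig(licenses={2017: 450.0, 2020: 550.0}),
        }
    )
    population_anchors: Optional[Dict[int, float]] = None
    output_dir: str = "results"
    bin_width: int = Field(5, ge=1)
    seed: int = 0

    @field_validator("population_anchors")
    @classmethod
    def _positive(cls, v):
        if v is not None:
            for year, pop in v.items():
                if pop <= 0:
                    raise ValueError(f"population anchor for {year} must be positive")
        return v

    def model_parameters(self) -> ModelParameters:
        overrides = {
            k: v for k, v in self.parameters.model_dump().items() if v is not None
        }
        return ModelParameters(**overrides)

    def projection(self) -> PopulationProjection:
        if self.population_anchors:
            return PopulationProjection(anchors=dict(self.population_anchors))
        return generate_population_anchors()

    def scenario(self, name: str) -> Scenario:
        if name not in self.scenarios:
            raise KeyError(
                f"scenario '{name}' not defined; available: {sorted(self.scenarios)}"
            )
        return self.scenarios[name].to_scenario(name)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML config; empty file means all defaults."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping, got {type(raw).__name__}")
    return RunConfig.model_validate(raw)


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write a config back to YAML (round-trips through load_config)."""
    payload = config.model_dump(exclude_none=True)
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))
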