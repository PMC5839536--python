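"""Configuration containers and the default parameter file.

All behavioural constants of the model live in one versioned YAML file
(``data/defaults.yaml``) plus the JSON coefficient/points/utility tables.
This module loads and validates them into typed objects used across the
package.  Nothing downstream hard-codes a parameter value.
"""

from __future__ import annotations

import json
from importlib import resources
from typing import Any

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

FACTORS = ("sbp", "dbp", "tc", "hdl", "bmi", "hba1c")
SMOKING_LEVELS = ("never", "ex", "current")
SEXES = ("male", "female")
DISEASES = ("ihd", "stroke", "dementia", "lung_cancer")


class ConfigurationError(ValueError):
    """Raised when a configuration value violates its invariants."""


def _data_text(name: str) -> str:
    return resources.files("healthchecksim.data").joinpath(name).read_text()


def load_default_config() -> dict[str, Any]:
    """Load the packaged default configuration as a plain dict."""
    return yaml.safe_load(_data_text("defaults.yaml"))


def load_json_data(name: str) -> dict[str, Any]:
    return json.loads(_data_text(name))


class PopulationSpec(BaseModel):
    """Specification of the synthetic baseline cohort aged 40-45.

    Categorical marginals must each sum to one; continuous risk factors are
    drawn from a Gaussian copula over log-transformed values.
    """

    model_config = ConfigDict(extra="forbid")

    n_individuals: int = Field(ge=0)
    age_min: int = 40
    age_max: int = 45
    category_marginals: dict[str, dict[str, float]]
    continuous: dict[str, Any]
    deprivation_effects: dict[str, float] = Field(default_factory=dict)
    condition_prevalence: dict[str, dict[str, Any]] = Field(default_factory=dict)
    seed: int = 0

    @field_validator("category_marginals")
    @classmethod
    def _marginals_sum_to_one(cls, v: dict[str, dict[str, float]]) -> dict:
        for name, marg in v.items():
            total = sum(marg.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"marginal '{name}' sums to {total!r}, expected 1.0"
                )
            if any(p < 0 for p in marg.values()):
                raise ConfigurationError(f"marginal '{name}' has negative entries")
        return v

    @model_validator(mode="after")
    def _check_continuous(self) -> "PopulationSpec":
        if self.age_min > self.age_max:
            raise ConfigurationError("age_min exceeds age_max")
        scales = self.continuous.get("log_scale", {})
        for f in FACTORS:
            if f not in scales:
                raise ConfigurationError(f"missing log_scale for factor '{f}'")
            if scales[f] <= 0:
                raise ConfigurationError(f"log_scale for '{f}' must be positive")
        for cond, cp in self.condition_prevalence.items():
            t = cp.get("target", 0.0)
            if not 0.0 <= t <= 1.0:
                raise ConfigurationError(f"prevalence target for '{cond}' outside [0,1]")
        corr = np.asarray(self.continuous.get("correlation"), dtype=float)
        if corr.shape != (len(FACTORS), len(FACTORS)):
            raise ConfigurationError("correlation matrix has wrong shape")
        if np.linalg.eigvalsh(corr).min() < -1e-10:
            raise ConfigurationError("correlation matrix is not positive semidefinite")
        return self

    @classmethod
    def from_config(cls, config: dict[str, Any] | None = None, **overrides) -> "PopulationSpec":
        from pydantic import ValidationError

        config = config if config is not None else load_default_config()
        pop = dict(config["population"])
        pop.update(overrides)
        try:
            return cls(**pop)
        except ValidationError as exc:
            raise ConfigurationError(str(exc)) from exc


class DynamicsParams(BaseModel):
    """Longitudinal donor-panel dynamics: AR(1) deviations around an age trend."""

    model_config = ConfigDict(extra="forbid")

    n_persons: int = Field(ge=1)
    n_waves: int = Field(ge=2)
    age_min: int = 40
    age_max: int = 95
    wave_years: int = 2
    ar_rho: float = Field(ge=0.0, lt=1.0)
    age_trend: dict[str, float]
    deviation_sd: dict[str, float]
    smoking_quit_prob_per_wave: float = Field(ge=0.0, le=1.0)
    smoking_relapse_prob_per_wave: float = Field(ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _check(self) -> "DynamicsParams":
        for f in FACTORS:
            if self.deviation_sd.get(f, -1.0) < 0:
                raise ConfigurationError(f"deviation_sd for '{f}' missing or negative")
        return self

    @classmethod
    def from_config(cls, config: dict[str, Any] | None = None, **overrides) -> "DynamicsParams":
        config = config if config is not None else load_default_config()
        d = dict(config["panel"])
        d.update(overrides)
        return cls(**d)


class Uncertain(BaseModel):
    """A parameter with a point value and a 95% credible interval."""

    value: float
    lo: float
    hi: float

    @model_validator(mode="after")
    def _check(self) -> "Uncertain":
        if not self.lo <= self.value <= self.hi:
            raise ConfigurationError(
                f"credible interval ({self.lo}, {self.hi}) does not bracket {self.value}"
            )
        return self


def get_in(d: dict, *keys, default=None):
    """Nested dict lookup: get_in(cfg, 'health_check', 'offer', 'annual_prob')."""
    cur: Any = d
    for k in keys:
        if not isinstance(cur, dict) or k not in cur:
            return default
        cur = cur[k]
    return cur


def set_in(d: dict, keys: tuple, value) -> None:
    cur = d
    for k in keys[:-1]:
        cur = cur.setdefault(k, {})
    cur[keys[-1]] = value
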