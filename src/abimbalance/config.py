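"""Run configuration: a single YAML/JSON file validated before any work.

Unknown keys are rejected with the offending key named (pydantic
``extra="forbid"``).  CLI flags override file values, which override the
defaults; the resolved configuration is hashed into every run log.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .simulate import SimulationConfig

__all__ = ["FitConfig", "AnalysisConfig", "CalibrationEntry", "CriteriaConfig", "RunConfig", "load_config"]


class FitConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    form: str = "rational"
    axis_scaling: str | tuple[float, float] | None = None
    objective: str = "l1"
    n_restarts: int = Field(default=20, ge=1)
    seed: int = 20240611
    domain: tuple[float, float] | None = None
    grid_size: int = Field(default=512, ge=16)
    proj_tol: float = Field(default=1e-8, gt=0)
    maxfev: int = Field(default=3000, ge=100)

    def estimator_kwargs(self) -> dict:
        return {
            "form": self.form,
            "scaling": self.axis_scaling,
            "objective": self.objective,
            "n_restarts": self.n_restarts,
            "random_state": self.seed,
            "domain": self.domain,
            "grid_size": self.grid_size,
            "proj_tol": self.proj_tol,
            "maxfev": self.maxfev,
        }


class CalibrationEntry(BaseModel):
    """Placeholder example entries ship in the default config; real slopes
    and intercepts are pipeline-specific configuration data."""

    model_config = ConfigDict(extra="forbid")
    tracer: str
    slope: float = Field(gt=0)
    intercept: float
    reference_region: str = "whole_cerebellum"
    target_region: str = "GAAIN_cortical"


class CriteriaConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    max_cdr: float = 0.0
    min_mmse_exclusive: float = 27.0
    exclude_apoe_e4_carriers: bool = True
    max_age: float = 70.0
    max_centiloid_exclusive: float = 12.0
    visit: str | None = "baseline"


class AnalysisConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    strata: tuple[str, ...] = ("all", "CU", "CI")
    interactions: bool = True
    fdr: bool = True
    min_n: int = 50
    sensitivity_ab42_40: bool = False


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seed: int = 20240611
    output_dir: str = "abimbalance_out"
    cohort_path: str | None = None
    visits_path: str | None = None
    model_path: str | None = None
    column_dictionary: dict = Field(default_factory=dict)
    fit: FitConfig = FitConfig()
    calibrations: list[CalibrationEntry] = Field(
        default_factory=lambda: [
            CalibrationEntry(tracer="example_identity", slope=1.0, intercept=0.0)
        ]
    )
    reference_criteria: CriteriaConfig = CriteriaConfig()
    simulation: SimulationConfig = SimulationConfig()
    analysis: AnalysisConfig = AnalysisConfig()

    def resolved_dict(self) -> dict:
        return json.loads(self.model_dump_json())


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML or JSON run config; ``overrides`` win over file values."""
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config root must be a mapping")
    for key, val in (overrides or {}).items():
        if val is None:
            continue
        node = data
        parts = key.split(".")
        for p in parts[:-1]:
            node = node.setdefault(p, {})
        node[parts[-1]] = val
    return RunConfig(**data)
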