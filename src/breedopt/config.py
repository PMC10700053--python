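"""Validated run configuration (YAML or JSON) with documented defaults.

Every block mirrors one pipeline stage; unknown keys are rejected so a
typo cannot silently fall back to a default.  An empty file yields the
standard toy-scheme setup: 10,000,000 budget with 4,000 / 3,000 per-head
costs, bounds 100-700 test bulls and 3-30 sires, inbreeding weight 50,
gain bandwidths (30, 1) divided by 3 for f, and a halving schedule.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from .search_space import BudgetModel, ParameterBounds
from .simulator import SchemeConfig, SimulatorObjective, TargetSpec
from .optimizer import PipelineConfig

__all__ = ["ConfigError", "RunConfig", "load_config"]


class ConfigError(ValueError):
    """Configuration file missing or failing schema validation."""


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class BudgetBlock(_Block):
    total: float = 10_000_000.0
    cost_cow: float = 4_000.0
    cost_bull: float = 3_000.0

    def to_model(self) -> BudgetModel:
        return BudgetModel(self.total, self.cost_cow, self.cost_bull)


class BoundsBlock(_Block):
    x2: tuple[int, int] = (100, 700)
    x3: tuple[int, int] = (3, 30)

    def to_model(self) -> ParameterBounds:
        return ParameterBounds(self.x2[0], self.x2[1], self.x3[0], self.x3[1])


class SchemeBlock(_Block):
    years: int = 15
    heritability: float = 0.3
    additive_variance: float = 1.0
    founder_cows: int | None = None
    founder_bulls: int | None = None
    dam_replacement_fraction: float = 0.25

    def to_model(self) -> SchemeConfig:
        return SchemeConfig(
            years=self.years,
            heritability=self.heritability,
            additive_variance=self.additive_variance,
            founder_cows=self.founder_cows,
            founder_bulls=self.founder_bulls,
            dam_replacement_fraction=self.dam_replacement_fraction,
        )


class TargetBlock(_Block):
    inbreeding_weight: float = 50.0
    horizon_weights: dict[int, float] | None = None

    def to_model(self) -> TargetSpec:
        return TargetSpec(self.inbreeding_weight, self.horizon_weights)


class SmoothingBlock(_Block):
    h0: tuple[float, float] = (30.0, 1.0)
    f_divisor: float = 3.0
    compose: bool = True
    mass_floor_rel: float = 1e-3
    cv: bool = False
    cv_candidates: list[tuple[float, float]] | None = None

    @field_validator("h0")
    @classmethod
    def _positive_h(cls, v):
        if any(x <= 0 for x in v):
            raise ValueError("bandwidths must be strictly positive")
        return v

    @field_validator("f_divisor")
    @classmethod
    def _positive_div(cls, v):
        if v <= 0:
            raise ValueError("f_divisor must be strictly positive")
        return v


class OptimizerBlock(_Block):
    n_per_iteration: tuple[int, ...] = (60_000, 50_000, 12_000)
    shrink_factor: float = 0.5
    padding: float = 0.5
    tolerance: tuple[int, int] = (1, 1)
    max_iterations: int | None = None
    min_separation: float = 0.0
    maxima_drop_frac: float = 0.05
    objective: Literal["simulator", "synthetic"] = "simulator"

    @field_validator("n_per_iteration")
    @classmethod
    def _positive_counts(cls, v):
        if not v or any(x < 1 for x in v):
            raise ValueError("simulation counts must be positive")
        return v


class SyntheticBlock(_Block):
    center: tuple[int, int] = (400, 15)
    curvature: tuple[float, float] = (0.005, 1.0)
    peak: float = 10.0
    noise_sd_g: float = 1.0
    noise_sd_f: float = 0.005


class EvaluationBlock(_Block):
    n_records: int = 60_000
    n_boot: int = 100
    subsample_size: int = 30_000
    sizes: tuple[int, ...] = (1_000, 10_000, 20_000, 60_000)
    n_rep: int = 100
    region: tuple[int, int, int, int] = (130, 210, 15, 21)


class RunConfig(_Block):
    budget: BudgetBlock = Field(default_factory=BudgetBlock)
    bounds: BoundsBlock = Field(default_factory=BoundsBlock)
    scheme: SchemeBlock = Field(default_factory=SchemeBlock)
    target: TargetBlock = Field(default_factory=TargetBlock)
    smoothing: SmoothingBlock = Field(default_factory=SmoothingBlock)
    optimizer: OptimizerBlock = Field(default_factory=OptimizerBlock)
    evaluation: EvaluationBlock = Field(default_factory=EvaluationBlock)
    synthetic: SyntheticBlock = Field(default_factory=SyntheticBlock)
    seed: int = 0
    output_dir: str = "."

    def pipeline_config(self) -> PipelineConfig:
        return PipelineConfig(
            n_per_iteration=self.optimizer.n_per_iteration,
            h0=self.smoothing.h0,
            f_divisor=self.smoothing.f_divisor,
            shrink_factor=self.optimizer.shrink_factor,
            padding=self.optimizer.padding,
            tolerance=self.optimizer.tolerance,
            max_iterations=self.optimizer.max_iterations,
            min_separation=self.optimizer.min_separation,
            maxima_drop_frac=self.optimizer.maxima_drop_frac,
            compose=self.smoothing.compose,
            mass_floor_rel=self.smoothing.mass_floor_rel,
        )

    def objective(self):
        if self.optimizer.objective == "simulator":
            return SimulatorObjective(
                config=self.scheme.to_model(),
                target=self.target.to_model(),
                budget=self.budget.to_model(),
            )
        from .evaluation import SyntheticObjective

        s = self.synthetic
        return SyntheticObjective.quadratic(
            center=s.center,
            curvature=s.curvature,
            peak=s.peak,
            noise_sd_g=s.noise_sd_g,
            noise_sd_f=s.noise_sd_f,
            inbreeding_weight=self.target.inbreeding_weight,
        )

    def digest(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


def _format_errors(exc: ValidationError) -> str:
    lines = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        lines.append(f"{loc}: {err['msg']}")
    return "; ".join(lines)


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML/JSON run configuration.

    ``None`` or an empty file produce the full default configuration;
    validation failures raise :class:`ConfigError` naming the offending
    key path.
    """
    if path is None:
        return RunConfig()
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"configuration root must be a mapping, got {type(raw).__name__}")
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(_format_errors(exc)) from exc
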