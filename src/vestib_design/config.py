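"""Run configuration: YAML in, validated model/design settings out.

Defaults reproduce the published study settings: Table-1 physical constants,
nominal theta = (0.85, 0.2), the 3 x 5 duration/angle grid, N = 100
maneuvers.  Unknown keys are rejected.
"""

from __future__ import annotations

import math
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .model import ParameterVector, PhysicalConstants
from .optimizers import (
    DEFAULT_ALPHA_GRID,
    DEFAULT_BOUNDS,
    DEFAULT_DT_GRID,
    DesignSpace,
)

__all__ = ["RunConfig", "load_config"]


class ConstantsConfig(BaseModel):
    """Overrides for :class:`PhysicalConstants` (CGS units)."""

    model_config = ConfigDict(extra="forbid")

    rho: float = 1.0
    rho_s: float = 2.7
    rho_e: float = 1.0
    mu_e: float = 8.5e-3
    g: float = 981.0
    A_s: float = 3.14e-4
    area_ratio: float = 1e-4
    r: float = 0.1
    l_n: float = 0.5
    n_particles: int = 6
    xi_dot: float = 0.02
    xi_0: float = 0.0
    a: float = 0.0
    b: float = 0.0

    def build(self) -> PhysicalConstants:
        return PhysicalConstants(**self.model_dump())


class SpaceConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    mode: str = "finite"
    dt_grid: tuple[float, ...] = DEFAULT_DT_GRID
    alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID
    bounds: tuple[tuple[float, float], tuple[float, float]] = DEFAULT_BOUNDS

    def build(self) -> DesignSpace:
        return DesignSpace(self.mode, self.dt_grid, self.alpha_grid,
                           tuple(map(tuple, self.bounds)))


class RunConfig(BaseModel):
    """Validated configuration for a full reproduction run."""

    model_config = ConfigDict(extra="forbid")

    constants: ConstantsConfig = Field(default_factory=ConstantsConfig)
    theta1: float = 0.85
    theta2: float = 0.2
    space: SpaceConfig = Field(default_factory=SpaceConfig)
    c_vectors: tuple[tuple[float, float], ...] = ((1.0, 0.0), (0.0, 1.0),
                                                  (1.0, 1.0))
    n_total: int = 100
    forcing_window: str = "literal"
    equivalence_tol: float = 1e-6
    table_tol: float = 5e-3
    elfving_resolution: int = 400
    robustness_theta1: tuple[float, ...] = (0.1, 0.7, 0.85, 0.9, 2.0)
    robustness_theta2: tuple[float, ...] = (0.015, 0.2, 0.9)
    out_dir: str = "results"

    @field_validator("forcing_window")
    @classmethod
    def _window(cls, v: str) -> str:
        if v not in ("literal", "shifted"):
            raise ValueError("forcing_window must be 'literal' or 'shifted'")
        return v

    @field_validator("n_total")
    @classmethod
    def _n(cls, v: int) -> int:
        if v < 1:
            raise ValueError("n_total must be >= 1")
        return v

    def physical_constants(self) -> PhysicalConstants:
        return self.constants.build()   # re-validates positivity

    def theta(self) -> ParameterVector:
        return ParameterVector(self.theta1, self.theta2)

    def design_space(self) -> DesignSpace:
        return self.space.build()

    def continuous_space(self) -> DesignSpace:
        return DesignSpace("continuous", bounds=self.space.bounds)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Parse a YAML config file; an empty/missing document keeps every
    default.  Schema violations raise with the offending keys listed."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw)}")
    cfg = RunConfig(**raw)
    cfg.physical_constants()  # surface constant-positivity errors eagerly
    math.isfinite(cfg.theta1) and cfg.theta()
    return cfg
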