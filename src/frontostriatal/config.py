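"""Schema-validated run configuration for the command-line interface.

A run is configured by an optional YAML file with one block per
subcommand; command-line flags override file values.  Unknown keys are
rejected before any computation.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .errors import DomainError

__all__ = [
    "EquilibriumSweepConfig",
    "CalibrateConfig",
    "OptimumDoseConfig",
    "OutcomeConfig",
    "RunConfig",
    "load_run_config",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class EquilibriumSweepConfig(_Strict):
    x_p_min: float = Field(0.05, gt=0)
    x_p_max: float = Field(0.95, gt=0)
    n_points: int = Field(91, ge=1)
    a: float = Field(0.0, ge=0)
    b_values: list[float] = [0.0, 0.25, 0.5, 0.75, 1.0]
    j_d: float = Field(1.0, gt=0)


class CalibrateConfig(_Strict):
    table: str | None = None  # path to an occupancy CSV; packaged table if None
    b_max_sz: float = Field(1.2, gt=0)
    a_values: list[float] = [0.0, 0.2, 0.4]
    b_grid_max: float = Field(1.0, ge=0)
    b_grid_points: int = Field(21, ge=2)


class OptimumDoseConfig(_Strict):
    model: Literal[1, 2] = 1


class OutcomeConfig(_Strict):
    input: str | None = None  # CSV with beta, delta_panss_pos; synthetic if None
    alpha: float = Field(0.3, ge=0, lt=1)
    a: float = Field(0.0, ge=0)
    b: float = Field(0.0, ge=0)
    n: int = Field(14, ge=3)
    noise_sd: float = Field(0.0, ge=0)
    seed: int = 0


class RunConfig(_Strict):
    """Top-level config: one optional block per subcommand."""

    equilibrium_sweep: EquilibriumSweepConfig = EquilibriumSweepConfig()
    calibrate: CalibrateConfig = CalibrateConfig()
    optimum_dose: OptimumDoseConfig = OptimumDoseConfig()
    outcome: OutcomeConfig = OutcomeConfig()


def load_run_config(path: str | Path | None) -> RunConfig:
    """Parse and validate a YAML run configuration (defaults if ``path`` is None)."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    try:
        return RunConfig(**raw)
    except ValidationError as e:
        raise DomainError(f"invalid run configuration {path}: {e}") from e
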