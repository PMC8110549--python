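"""Validated run configuration (JSON).

The configuration format is JSON and is considered stable.  Every field
has a default; an empty file (or ``{}``) yields the reference
two-oscillator setup (hub at 1, leaf at 0.5, detuning 0.5, alpha 1,
tau_plus 0.15, tau_minus 0.3, epsilon 1e-3, sigmoid boundary mu 0.01).
Validation errors enumerate every offending field (pydantic).
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .model import BoundarySpec, NetworkParams

__all__ = ["BoundaryConfig", "ModelConfig", "SolverConfig", "SurveyConfig",
           "RunConfig", "load_config", "config_digest"]


class BoundaryConfig(BaseModel):
    family: Literal["power", "sigmoid", "heaviside"] = "sigmoid"
    mu: float = Field(default=0.01, gt=0)


class ModelConfig(BaseModel):
    omega0: float = 1.0
    omega: list[float] = Field(default_factory=lambda: [0.5], min_length=1)
    alpha: float = Field(default=1.0, gt=0)
    tau_plus: float = Field(default=0.15, gt=0)
    tau_minus: float = Field(default=0.3, gt=0)
    epsilon: float = Field(default=1e-3, gt=0)
    boundary: BoundaryConfig = Field(default_factory=BoundaryConfig)

    @model_validator(mode="after")
    def _check(self) -> "ModelConfig":
        if any(b <= a for a, b in zip(self.omega, self.omega[1:])):
            raise ValueError("leaf frequencies must be strictly ascending and distinct")
        if self.omega0 in self.omega:
            raise ValueError("hub frequency must differ from every leaf frequency")
        if self.tau_plus >= self.tau_minus:
            raise ValueError("need tau_minus > tau_plus (depression window longer)")
        return self


class SolverConfig(BaseModel):
    method: Literal["rk4", "rk45"] = "rk4"
    dt: float = Field(default=0.01, gt=0)
    t_end: float | None = Field(default=None, gt=0)
    record_every: float | None = Field(default=None, gt=0)
    rtol: float = Field(default=1e-8, gt=0)
    atol: float = Field(default=1e-10, gt=0)


class SurveyConfig(BaseModel):
    count: int = Field(default=200, ge=1)
    seed: int = 0
    distance: float = Field(default=0.05, gt=0)
    threshold_fraction: float = Field(default=0.5, gt=0, lt=1)
    checkpoint_times: list[float] = Field(default_factory=lambda: [300.0, 8000.0])


class RunConfig(BaseModel):
    model: ModelConfig = Field(default_factory=ModelConfig)
    solver: SolverConfig = Field(default_factory=SolverConfig)
    survey: SurveyConfig = Field(default_factory=SurveyConfig)
    output_dir: str = "starpddp_out"

    def network_params(self) -> NetworkParams:
        m = self.model
        return NetworkParams(
            omega0=m.omega0, omega=np.asarray(m.omega), alpha=m.alpha,
            tau_plus=m.tau_plus, tau_minus=m.tau_minus, epsilon=m.epsilon,
            boundary=BoundarySpec(family=m.boundary.family, mu=m.boundary.mu))

    def t_end(self) -> float:
        """Configured horizon, defaulting to the 100/epsilon saturation scale."""
        return self.solver.t_end if self.solver.t_end is not None \
            else 100.0 / self.model.epsilon


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a JSON run configuration.

    ``None`` or an empty file produces the pure-default configuration.
    """
    if path is None:
        return RunConfig()
    text = Path(path).read_text().strip()
    if not text:
        return RunConfig()
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ValueError(f"config {path} is not valid JSON: {exc}") from exc
    return RunConfig.model_validate(data)


def config_digest(cfg: RunConfig) -> str:
    """Stable hash of a configuration, for run manifests."""
    canonical = json.dumps(cfg.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()
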