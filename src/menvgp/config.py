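"""Run configuration: a versioned YAML schema with strict validation.

Unknown keys are rejected rather than ignored — silent misconfiguration is
the main reproducibility hazard in a multi-stage pipeline.  One global
seed fans out deterministically to every stochastic stage.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class SimSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_lines: int = 400
    n_markers: int = 2000
    maf_low: float = 0.05
    maf_high: float = 0.5
    n_envs: int = 4
    n_reps: int = 2
    env_corr: float = 0.8
    h2_per_env: list[float] | None = None
    spatial_amplitude: float = 1.0
    missing_cell_fraction: float = 0.10
    n_covs: int = 3


class QCSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    maf_max_removed: float = 0.05
    miss_max: float = 0.10
    corr_max: float = 0.99


class MCMCSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_iter: int = 20000
    burn_in: int = 8000
    thin: int = 5

    @model_validator(mode="after")
    def _check(self):
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        return self


class CVSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    schemes: list[str] = Field(default_factory=lambda: ["single_env", "cv1", "cv2"])
    n_reps: int = 100
    frac_test: float = 0.2


class RunConfig(BaseModel):
    """Top-level configuration for the `menvgp` pipeline."""

    model_config = ConfigDict(extra="forbid")
    schema_version: int = 1
    seed: int = 0
    trait: str = "trait"
    output_dir: str = "menvgp_run"
    genotypes: str | None = None  # path; None -> simulate
    phenotypes: str | None = None
    ecs: str | None = None
    models: list[str] = Field(
        default_factory=lambda: ["gblup", "gxc", "mxe", "mtm1", "mtm2"]
    )
    simulate: SimSettings = Field(default_factory=SimSettings)
    qc: QCSettings = Field(default_factory=QCSettings)
    mcmc: MCMCSettings = Field(default_factory=MCMCSettings)
    cv: CVSettings = Field(default_factory=CVSettings)

    @model_validator(mode="after")
    def _check(self):
        if not self.trait:
            raise ValueError("trait name must be set")
        if self.schema_version != 1:
            raise ValueError(f"unsupported schema_version {self.schema_version}")
        return self

    def stage_seed(self, stage: int) -> int:
        """Deterministic per-stage seed derived from the global seed."""
        ss = np.random.SeedSequence(entropy=self.seed, spawn_key=(stage,))
        return int(ss.generate_state(1)[0] % (2 ** 31))


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=False))
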