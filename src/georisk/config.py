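"""Pipeline configuration, validated with pydantic before any stage runs."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = ["PipelineConfig", "SimulateConfig", "ModelConfig", "MCConfig",
           "load_config"]


class SimulateConfig(BaseModel):
    enabled: bool = True
    extent_km: tuple[float, float] = (90.0, 90.0)
    resolution_km: float = Field(6.0, gt=0)
    n_strata: int = Field(9, ge=1)
    clusters_per_stratum: int = Field(8, ge=1)
    persons_per_cluster_mean: float = Field(148.0, gt=0)
    # generative truth on the log-incidence scale (bite model layout)
    beta: list[float] = [-6.6239, 0.0032, -0.0046, 0.2225, 0.5586,
                         -0.0002, 7.2235, -6.4166]
    sigma2: float = Field(0.189, ge=0)
    phi: float = Field(15.0, gt=0)
    tau2: float = Field(0.304, ge=0)

    @field_validator("extent_km")
    @classmethod
    def _positive_extent(cls, v):
        if v[0] <= 0 or v[1] <= 0:
            raise ValueError("extent must be positive")
        return v


class ModelConfig(BaseModel):
    response: str = "bites"
    elevation_knot: float = 160.0
    agri_knot: float = 0.09
    scan_breakpoints: bool = False
    elevation_scan_step: float = Field(5.0, gt=0)
    agri_scan_step: float = Field(0.01, gt=0)

    @field_validator("response")
    @classmethod
    def _known_response(cls, v):
        if v not in ("bites", "envenoming"):
            raise ValueError("response must be 'bites' or 'envenoming'")
        return v


class MCConfig(BaseModel):
    n_burn: int = Field(500, ge=0)
    thin: int = Field(4, ge=1)
    n_keep: int = Field(250, ge=1)
    max_reanchor: int = Field(10, ge=1)
    rel_tol: float = Field(1e-2, gt=0)


class PipelineConfig(BaseModel):
    seed: int = 0
    outdir: str = "georisk_output"
    clusters_path: str | None = None
    strata_path: str | None = None
    grid_path: str | None = None
    simulate: SimulateConfig = SimulateConfig()
    model: ModelConfig = ModelConfig()
    mc: MCConfig = MCConfig()
    thresholds: list[float] = [300.0, 398.0, 500.0]
    grid_resolution_km: float = Field(5.0, gt=0)

    @field_validator("thresholds")
    @classmethod
    def _positive_thresholds(cls, v):
        if not v or any(t <= 0 for t in v):
            raise ValueError("thresholds must be positive and non-empty")
        return v

    @model_validator(mode="after")
    def _inputs_available(self):
        if not self.simulate.enabled:
            if not (self.clusters_path and self.strata_path):
                raise ValueError(
                    "clusters_path and strata_path are required when "
                    "simulation is disabled")
        return self

    def content_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    """Load a YAML or JSON config file."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    data = (json.loads(text) if path.suffix.lower() == ".json"
            else yaml.safe_load(text))
    return PipelineConfig.model_validate(data or {})
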