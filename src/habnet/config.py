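"""YAML run configuration with schema validation.

One YAML file drives an entire study: the synthetic-landscape generator,
patch delineation, the dispersal kernel, the sampling-intensity labelling,
the boosted-tree settings and the distance sweep. Validation is by pydantic
models; every error names the offending key, and defaults follow the
analysis conventions (kernel shape p = 0.5, edge cutoff 1e-4, learning rate
0.001, tree complexity 5, bag fraction 0.75).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

__all__ = ["RunConfig", "validate_config", "config_hash"]


class LandscapeSection(BaseModel):
    grid_width: int = 256
    grid_height: int = 256
    cell_size: float = 100.0
    suitability_correlation_length: float = 500.0
    n_water_sites: int = 1500
    water_buffer: float = 120.0


class OccupancySection(BaseModel):
    true_d0: float = 301.0
    intercept: float = -12.0
    beta_hsi: float = 8.0
    beta_logarea: float = 0.5
    beta_connectivity: float = 2.0
    n_settle_iterations: int = 5

    @field_validator("true_d0")
    @classmethod
    def _d0_positive(cls, v):
        if v <= 0:
            raise ValueError("true_d0 must be positive")
        return v


class SamplingSection(BaseModel):
    mean_visits_per_patch: float = 3.0
    detection_prob_per_visit: float = 0.7
    n_target_group_species: int = 13
    focal_species: str = "focal"


class DelineationSection(BaseModel):
    binarization_threshold: float = 0.6
    connectivity: int = 8


class KernelSection(BaseModel):
    p: float = 0.5
    prob_min: float = 1e-4
    d0: float | None = None  # set per distance when sweeping

    @field_validator("p", "prob_min")
    @classmethod
    def _unit_interval(cls, v):
        if not 0 < v < 1:
            raise ValueError("kernel probabilities must be in (0, 1)")
        return v

    @field_validator("d0")
    @classmethod
    def _d0_positive(cls, v):
        if v is not None and v <= 0:
            raise ValueError("d0 must be positive")
        return v


class BRTSection(BaseModel):
    learning_rate: float = 0.001
    tree_complexity: int = 5
    bag_fraction: float = 0.75
    n_folds: int = 10
    step_size: int = 50
    max_trees: int = 10000
    patience: int = 5
    n_replicates: int = 100


class SweepSection(BaseModel):
    species: list[str] = Field(default_factory=lambda: ["focal"])
    fixed_distances: list[float] = Field(
        default_factory=lambda: [300.0, 1000.0, 2000.0, 4000.0, 6000.0, 8000.0, 10000.0]
    )
    species_specific_distance: dict[str, float] = Field(default_factory=dict)
    intensity_threshold: int | None = None
    snap_distance: float = 0.0


class RunConfig(BaseModel):
    seed: int = 0
    output_dir: str = "habnet_out"
    suitability_path: str | None = None  # None -> synthetic
    mask_path: str | None = None
    observations_path: str | None = None
    landscape: LandscapeSection = Field(default_factory=LandscapeSection)
    occupancy_truth: OccupancySection = Field(default_factory=OccupancySection)
    sampling: SamplingSection = Field(default_factory=SamplingSection)
    delineation: DelineationSection = Field(default_factory=DelineationSection)
    kernel: KernelSection = Field(default_factory=KernelSection)
    brt: BRTSection = Field(default_factory=BRTSection)
    sweep: SweepSection = Field(default_factory=SweepSection)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)


def validate_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration.

    Missing sections take their defaults; referenced input files must
    exist. All violations are reported together, each naming its key.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig.model_validate(raw)  # pydantic lists every bad key
    missing = [
        (key, p)
        for key, p in [
            ("suitability_path", cfg.suitability_path),
            ("mask_path", cfg.mask_path),
            ("observations_path", cfg.observations_path),
        ]
        if p is not None and not Path(p).exists()
    ]
    if missing:
        raise ValueError(
            "; ".join(f"{key}: file not found: {p}" for key, p in missing)
        )
    return cfg


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
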