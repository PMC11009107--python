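"""Schema-versioned pipeline configuration (validated, unknown keys rejected)."""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field

__all__ = [
    "PipelineConfig",
    "SimulateStage",
    "DetectStage",
    "FilterStage",
    "ClassifyStage",
    "HydrolysateStage",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateStage(_Strict):
    """What to put in the simulated chamber and how to record it."""

    analytes: dict[str, float] = Field(default_factory=dict)  # class -> µM
    duration_s: float = 60.0
    sampling_rate: float = 2000.0
    noise_sd: float = 1.0
    baseline_current: float = 100.0
    copper_occupancy: float = 0.878
    artifact_rate_per_min: float = 3.0  # blank-control artifacts
    train_experiments_per_class: int = 2
    train_duration_s: float = 60.0


class DetectStage(_Strict):
    penalty: float | None = None
    min_blockade: float = 0.1
    min_dwell_ms: float = 0.5


class FilterStage(_Strict):
    enabled: bool = True
    k: int = 10


class ClassifyStage(_Strict):
    algorithm: str = "rf"
    cv_folds: int = 10
    probability_threshold: float = 0.95
    per_class_target: int = 200


class HydrolysateStage(_Strict):
    peptide: str
    enzyme: str = "carboxypeptidase_a1"
    cleavage_rate_per_min: float = 1.0
    digestion_time_min: float = 1.5
    peptide_concentration_uM: float = 20.0


class PipelineConfig(_Strict):
    """Full end-to-end run configuration; persisted with every run."""

    schema_version: int = 1
    seed: int = 0
    simulate: SimulateStage = Field(default_factory=SimulateStage)
    detect: DetectStage = Field(default_factory=DetectStage)
    filter: FilterStage = Field(default_factory=FilterStage)
    classify: ClassifyStage = Field(default_factory=ClassifyStage)
    hydrolysate: HydrolysateStage | None = None

    def to_json(self) -> str:
        return json.dumps(self.model_dump(), indent=2, sort_keys=True)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))

    def write(self, path) -> None:
        Path(path).write_text(self.to_json())
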