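"""Pipeline configuration: one YAML document with full defaulting."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field

from .simulate import Protocol

__all__ = ["PipelineConfig", "load_config"]


class PipelineConfig(BaseModel):
    """Everything the screen needs beyond the data files.

    Defaults follow the assay conventions: cutoff 1 control SD, benchmark
    response 1.349 control SDs, activity at hitcall >= 0.9, plate rejected
    when > 15% of its vehicle controls are non-normal.
    """

    protocol: Protocol = Protocol()
    cutoff_multiplier: float = Field(default=1.0, gt=0)
    bmr_multiplier: float = Field(default=1.349, gt=0)
    hit_threshold: float = Field(default=0.9, ge=0, le=1)
    n_boot: int = Field(default=1000, ge=0)
    seed: int = 0
    qc_threshold: float = Field(default=0.15, gt=0, lt=1)
    alpha: float = Field(default=0.05, gt=0, lt=1)
    min_move_cm: float = Field(default=0.02, ge=0)
    reference_path: str | None = None  # optional pre-fit vehicle reference JSON

    def config_hash(self) -> str:
        doc = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(doc.encode()).hexdigest()[:12]


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML config; missing file or keys fall back to defaults."""
    if path is None:
        return PipelineConfig()
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    return PipelineConfig(**doc)
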