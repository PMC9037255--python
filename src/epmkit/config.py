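"""Pipeline configuration: schema-validated, defaults matching the published
analysis settings (top_k=30000, 100 consensus repetitions, 100 edge clusters,
min size 30, 0.5/0.7 characteristic rules, |logFC| 0.585 / 0.1, FDR 0.01,
Cox p 0.01)."""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    # inputs (None = stage skipped or synthetic preset used)
    tumor_expression: str | None = None
    normal_expression: str | None = None
    network: str | None = None
    clinical: str | None = None
    validation_tumor_expression: str | None = None
    validation_normal_expression: str | None = None
    validation_clinical: str | None = None
    methylation: str | None = None
    out_dir: str = "epm_out"
    seed: int = 17
    resume: bool = False

    # preprocessing
    zero_filter_threshold: float = Field(0.7, gt=0, le=1)

    # EPM
    benchmark: str = "rank_of_mean"
    feature_transform: str = "signed_log"

    # feature selection
    top_k: int = Field(30000, ge=1)

    # consensus clustering
    k_min: int = Field(2, ge=2)
    k_max: int = Field(6, ge=2)
    reps: int = Field(100, ge=2)
    p_item: float = Field(0.8, gt=0, le=1)
    chosen_k: int | None = None

    # characteristic clusters
    n_clusters: int = Field(100, ge=2)
    min_size: int = Field(30, ge=1)
    mean_cut: float = Field(0.5, ge=0)
    pct_cut: float = Field(0.7, ge=0, le=1)

    # differential screening
    lfc_cut: float = Field(0.585, ge=0)
    meth_lfc_cut: float = Field(0.1, ge=0)
    fdr_cut: float = Field(0.01, gt=0, le=1)

    # risk model
    cox_p_cut: float = Field(0.01, gt=0, le=1)
    n_folds: int = Field(10, ge=2)
    lambda_rule: str = "min"
    minprop: float = Field(0.1, gt=0, lt=0.5)
    horizons: list[float] = Field(default_factory=lambda: [1.0, 3.0, 5.0])

    @field_validator("benchmark")
    @classmethod
    def _benchmark(cls, v):
        if v not in ("rank_of_mean", "mean_of_delta"):
            raise ValueError("benchmark must be 'rank_of_mean' or 'mean_of_delta'")
        return v

    @field_validator("feature_transform")
    @classmethod
    def _transform(cls, v):
        if v not in ("signed_log", "abs_log"):
            raise ValueError("feature_transform must be 'signed_log' or 'abs_log'")
        return v

    @field_validator("lambda_rule")
    @classmethod
    def _rule(cls, v):
        if v not in ("min", "1se"):
            raise ValueError("lambda_rule must be 'min' or '1se'")
        return v


def validate_config(path) -> PipelineConfig:
    """Load and validate a YAML/JSON config file; an empty file yields the
    all-defaults configuration.  Unknown keys are rejected."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) if text.strip() else {}
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return PipelineConfig(**data)


def config_hash(cfg: PipelineConfig) -> str:
    import hashlib

    blob = json.dumps(cfg.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
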