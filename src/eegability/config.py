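"""Validated run configuration for the pipeline CLI.

Every stage's parameters live in one nested schema with the documented
defaults (5 folds, 5 repetitions, 20 fractions in [0.001, 0.99],
t threshold 1.96, alpha 0.05, repetition probability 0.1, 256 Hz,
−200..1,100 ms). Unknown keys are rejected with the offending path named,
as are out-of-range values.
"""

from __future__ import annotations

import json

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

__all__ = ["RunConfig", "validate_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryConfig(_Strict):
    name: str
    kind: str = "block"
    center_ms: float = 150.0
    width_ms: float = Field(30.0, gt=0)
    ability_coupling: float = 0.0
    amplitude: float = Field(1.0, ge=0)
    n_dims: int = Field(4, ge=1)
    categories: list[str] | None = None


def _default_geometries() -> list[GeometryConfig]:
    return [
        GeometryConfig(
            name="midlevel_visual", kind="block", center_ms=150.0, width_ms=20.0,
            ability_coupling=0.5,
        ),
        GeometryConfig(
            name="semantic", kind="category", center_ms=650.0, width_ms=50.0,
            ability_coupling=0.5,
        ),
    ]


class CohortConfig(_Strict):
    n_face: int = Field(24, ge=0)
    n_nonface: int = Field(25, ge=0)
    n_identities: int = Field(13, ge=1)
    n_super: int = Field(16, ge=0)
    n_typical: int = Field(17, ge=0)
    n_trials_per_participant: int = Field(3200, ge=1)
    n_channels: int = Field(128, ge=1)
    sampling_rate: float = Field(256.0, gt=0)
    epoch_window_ms: tuple[float, float] = (-200.0, 1100.0)
    noise_sd: float = Field(2.0, ge=0)
    jitter_sd: float = Field(1.0, ge=0)
    evoked_strength: float = Field(1.0, ge=0)
    noise_smoothing_ms: float = Field(0.0, ge=0)
    p_repeat: float = 0.1
    n_sessions: int = Field(2, ge=1)
    hit_rate: float = Field(0.85, ge=0, le=1)
    metadata_only: bool = False
    geometries: list[GeometryConfig] = Field(default_factory=_default_geometries)
    # pairwise |Spearman| allowed between planted geometry RDMs; tiny
    # stimulus sets need a looser bound than the 0.7 default
    geometry_correlation_bound: float = Field(0.7, gt=0, le=1)

    @field_validator("p_repeat")
    @classmethod
    def _p_repeat_range(cls, v):
        if not (0 <= v < 1):
            raise ValueError("p_repeat must lie in [0, 1)")
        return v


class PreprocessingConfig(_Strict):
    reference_channel: str | None = "Cz"
    band: tuple[float, float] | None = (0.01, 80.0)
    epoch_window_ms: tuple[float, float] = (-200.0, 1100.0)
    target_rate: float = Field(256.0, gt=0)
    baseline_window_ms: tuple[float, float] | None = None
    match_trials: bool = True


class DecodingConfig(_Strict):
    condition: str = "all"
    n_folds: int = Field(5, ge=2)
    n_repetitions: int = Field(5, ge=1)
    n_permutations: int = Field(1000, ge=0)
    grouped_cv: bool = False
    fractions: list[float] | None = None
    ability_split: tuple[float, float, float] = (0.6, 0.3, 0.1)
    ability_repetitions: int = Field(10, ge=1)
    ability_permutations: int = Field(0, ge=0)
    run_ability: bool = True

    @field_validator("fractions")
    @classmethod
    def _fractions_range(cls, v):
        if v is not None and any(f <= 0 or f > 1 for f in v):
            raise ValueError("fractions must lie in (0, 1]")
        return v

    @field_validator("condition")
    @classmethod
    def _condition_value(cls, v):
        if v not in ("face", "nonface", "all"):
            raise ValueError("condition must be 'face', 'nonface' or 'all'")
        return v


class RsaConfig(_Strict):
    rdm_folds: int = Field(5, ge=2)
    rdm_repetitions: int = Field(5, ge=1)
    t_threshold: float = Field(1.96, gt=0)
    alpha: float = Field(0.05, gt=0, lt=1)
    n_permutations: int = Field(1000, ge=1)


class RunConfig(_Strict):
    """Fully determines a pipeline run given its seed."""

    seed: int = Field(0, ge=0)
    output_dir: str = "eegability_out"
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    preprocessing: PreprocessingConfig = Field(default_factory=PreprocessingConfig)
    decoding: DecodingConfig = Field(default_factory=DecodingConfig)
    rsa: RsaConfig = Field(default_factory=RsaConfig)

    def config_hash(self) -> str:
        import hashlib

        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def validate_config(raw: str | dict | None) -> RunConfig:
    """Parse YAML/JSON text (or a dict) into a validated RunConfig.

    An empty document yields full defaults; unknown keys and out-of-range
    values raise ValueError naming the offending path.
    """
    if raw is None:
        data = {}
    elif isinstance(raw, dict):
        data = raw
    else:
        data = yaml.safe_load(raw) or {}
    if not isinstance(data, dict):
        raise ValueError("configuration must be a mapping")
    try:
        return RunConfig(**data)
    except ValidationError as err:
        lines = []
        for e in err.errors():
            path = ".".join(str(p) for p in e["loc"]) or "<root>"
            lines.append(f"{path}: {e['msg']}")
        raise ValueError("invalid configuration: " + "; ".join(lines)) from None
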