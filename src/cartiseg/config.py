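"""Schema-validated pipeline configuration (YAML or JSON).

Every CLI stage reads one config file with optional sections; unknown keys
anywhere in the file are rejected so typos fail loudly before any stage
runs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .augment import AugmentationPolicy
from .netarch import NetworkSpec
from .preprocess import CanvasSpec
from .trainer import SubsampleRule, TrainingConfig

__all__ = ["PipelineConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Raised when a configuration file fails schema validation."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CanvasSection(_Strict):
    height: int = 1792
    width: int = 1280
    target_voxel: float = 6.0

    def build(self) -> CanvasSpec:
        return CanvasSpec(self.height, self.width, self.target_voxel)


class NetworkSection(_Strict):
    input_height: int = 1792
    input_width: int = 1280
    depth: int = 6
    base_filters: int = 16
    filters_double_per_level: bool = True
    use_residual: bool = True
    use_deep_supervision: bool = True
    activation: str = "selu"
    supervision_weights: list[float] | None = None

    def build(self) -> NetworkSpec:
        w = tuple(self.supervision_weights) if self.supervision_weights else None
        return NetworkSpec(
            input_height=self.input_height, input_width=self.input_width,
            depth=self.depth, base_filters=self.base_filters,
            filters_double_per_level=self.filters_double_per_level,
            use_residual=self.use_residual,
            use_deep_supervision=self.use_deep_supervision,
            activation=self.activation, supervision_weights=w)


class TrainingSection(_Strict):
    learning_rate: float = 1e-4
    batch_size: int = 4
    epochs: int = 50
    amsgrad: bool = True
    seed: int = 0
    augment: bool = True
    subsample: bool = False
    background_stride: int = 200
    foreground_stride: int = 30

    def build(self) -> TrainingConfig:
        return TrainingConfig(learning_rate=self.learning_rate,
                              batch_size=self.batch_size, epochs=self.epochs,
                              amsgrad=self.amsgrad, seed=self.seed)

    def build_rule(self) -> SubsampleRule | None:
        if not self.subsample:
            return None
        return SubsampleRule(self.background_stride, self.foreground_stride)


class AugmentationSection(_Strict):
    rotation_range: tuple[float, float] = (-10.0, 10.0)
    gamma_range: tuple[float, float] = (0.9, 1.1)
    scale_range: tuple[float, float] = (0.9, 1.1)
    elastic_spacing: float = 128.0
    elastic_magnitude: float = 10.0
    pair_probabilities: list[list[float]] | None = None

    def build(self) -> AugmentationPolicy:
        kw = dict(rotation_range=self.rotation_range, gamma_range=self.gamma_range,
                  scale_range=self.scale_range, elastic_spacing=self.elastic_spacing,
                  elastic_magnitude=self.elastic_magnitude)
        if self.pair_probabilities is not None:
            kw["pair_probabilities"] = np.asarray(self.pair_probabilities)
        return AugmentationPolicy(**kw)


class CVSection(_Strict):
    k: int = 7
    seed: int = 0


class InferenceSection(_Strict):
    threshold: float = 0.5
    batch_size: int = 4


class ThicknessSection(_Strict):
    bin_width_um: float = 6.0


class PhantomSection(_Strict):
    n: int = 14
    n_mutant: int = 3
    n_poor_staining: int = 1
    seed: int = 0
    preset: str = "desk"  # "desk" or "full-scale"
    volume_shape: tuple[int, int, int] | None = None  # overrides the preset shape


class PipelineConfig(_Strict):
    schema_version: int = 1
    canvas: CanvasSection = Field(default_factory=CanvasSection)
    network: NetworkSection = Field(default_factory=NetworkSection)
    training: TrainingSection = Field(default_factory=TrainingSection)
    augmentation: AugmentationSection = Field(default_factory=AugmentationSection)
    cv: CVSection = Field(default_factory=CVSection)
    inference: InferenceSection = Field(default_factory=InferenceSection)
    thickness: ThicknessSection = Field(default_factory=ThicknessSection)
    phantom: PhantomSection = Field(default_factory=PhantomSection)

    @field_validator("schema_version")
    @classmethod
    def _version(cls, v):
        if v != 1:
            raise ValueError(f"unsupported schema_version {v}")
        return v


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML/JSON pipeline config; raises ConfigError
    with the schema path of the first failure."""
    path = Path(path)
    try:
        text = path.read_text()
        raw = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") \
            else json.loads(text)
    except Exception as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    try:
        return PipelineConfig.model_validate(raw or {})
    except Exception as exc:
        raise ConfigError(f"invalid config {path}: {exc}") from exc
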