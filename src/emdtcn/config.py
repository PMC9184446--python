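"""YAML pipeline configuration: nested blocks validated at load time."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .model import ModelConfig
from .pipeline import EmdConfig, PreprocessConfig
from .synth import ArtifactSpec, SyntheticConfig
from .traineval import TrainConfig

__all__ = ["PipelineConfig", "load_config"]


def _build(cls, block: dict, name: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(block) - allowed
    if unknown:
        raise ConfigurationError(
            f"unknown keys in '{name}' block: {sorted(unknown)}"
        )
    # tuples arrive from YAML as lists
    coerced = {}
    for f in fields(cls):
        if f.name in block:
            v = block[f.name]
            coerced[f.name] = tuple(v) if isinstance(v, list) and "tuple" in str(f.type) else v
    return cls(**coerced)


@dataclass
class PipelineConfig:
    """All tunables of a pipeline run, one nested block per stage."""

    synth: SyntheticConfig = field(default_factory=SyntheticConfig)
    artifacts: ArtifactSpec = field(default_factory=ArtifactSpec)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    emd: EmdConfig = field(default_factory=EmdConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    input_len: int = 100
    lead: int = 10

    def validate(self) -> None:
        self.synth.validate()
        self.preprocess.validate()
        self.emd.validate()
        self.model.validate(input_len=self.input_len)
        self.train.validate()
        if self.input_len < 1 or self.lead < 1:
            raise ConfigurationError("input_len and lead must be >= 1")


_BLOCKS = {
    "synth": SyntheticConfig,
    "artifacts": ArtifactSpec,
    "preprocess": PreprocessConfig,
    "emd": EmdConfig,
    "train": TrainConfig,
}


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML config file; missing blocks fall back to defaults and
    unknown keys are rejected."""
    if path is None:
        cfg = PipelineConfig()
        cfg.validate()
        return cfg
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = set(_BLOCKS) | {"model", "input_len", "lead"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown top-level config keys: {sorted(unknown)}")
    kwargs = {}
    for name, cls in _BLOCKS.items():
        if name in raw:
            kwargs[name] = _build(cls, raw[name] or {}, name)
    if "model" in raw:
        block = raw["model"] or {}
        allowed = {f.name for f in fields(ModelConfig)}
        unknown = set(block) - allowed
        if unknown:
            raise ConfigurationError(f"unknown keys in 'model' block: {sorted(unknown)}")
        kwargs["model"] = ModelConfig.from_dict(block)
    if "input_len" in raw:
        kwargs["input_len"] = int(raw["input_len"])
    if "lead" in raw:
        kwargs["lead"] = int(raw["lead"])
    cfg = PipelineConfig(**kwargs)
    cfg.validate()
    return cfg
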