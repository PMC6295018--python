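"""Pipeline configuration with strict (unknown-key-rejecting) YAML I/O."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from ..morphometry import MorphometryConfig
from ..scratch_assay import ScratchParams
from ..screen_stats import StatsConfig

__all__ = ["PipelineConfig"]


def _build(cls, data: dict, context: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown key(s) in {context}: {sorted(unknown)}")
    return cls(**data)


@dataclass
class PipelineConfig:
    """Everything the end-to-end screen pipeline needs, serialisable."""

    morphometry: MorphometryConfig = field(default_factory=MorphometryConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    scratch: ScratchParams = field(default_factory=ScratchParams)
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown key(s) in config: {sorted(unknown)}")
        kwargs = {}
        for name, sub_cls in (("morphometry", MorphometryConfig),
                              ("stats", StatsConfig),
                              ("scratch", ScratchParams)):
            if name in data:
                kwargs[name] = _build(sub_cls, data.pop(name) or {}, name)
        kwargs.update(data)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
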