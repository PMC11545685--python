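"""Run configuration: one YAML file resolving every stage's parameters.

A run config is a mapping with optional sections ``phantom``, ``quality``,
``saliency``, ``model``, ``train`` plus top-level ``seed`` and ``side``;
missing keys resolve to the package defaults. The resolved config is
serialized verbatim into every run directory together with its hash so a
run can be reproduced bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .model import ModelConfig
from .phantom import PhantomConfig
from .preprocess import QualityThresholds
from .saliency import SaliencyParams
from .train import TrainConfig

__all__ = ["RunConfig", "load_run_config"]


@dataclass
class RunConfig:
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    quality: QualityThresholds = field(default_factory=QualityThresholds)
    saliency: SaliencyParams = field(default_factory=SaliencyParams)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    seed: int = 0
    side: int = 256

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def resolved_yaml(self) -> str:
        return yaml.safe_dump(json.loads(json.dumps(self.to_dict())),
                              sort_keys=True)

    def hash(self) -> str:
        return hashlib.sha256(self.resolved_yaml().encode()).hexdigest()[:12]

    def dump(self, path) -> None:
        Path(path).write_text(self.resolved_yaml())


_SECTIONS = {
    "phantom": PhantomConfig,
    "quality": QualityThresholds,
    "saliency": SaliencyParams,
    "model": ModelConfig,
    "train": TrainConfig,
}


def load_run_config(path=None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus keyword overrides.

    Overrides use section-qualified keys (``model={"input_side": 128}``)
    or the top-level scalars ``seed`` / ``side``.
    """
    raw: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded:
            raw.update(loaded)
    for key, val in overrides.items():
        if key in _SECTIONS:
            raw.setdefault(key, {}).update(val)
        else:
            raw[key] = val
    kwargs = {}
    for name, cls in _SECTIONS.items():
        section = dict(raw.get(name) or {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(section) - known
        if unknown:
            raise ValueError(f"unknown keys in '{name}' config: {sorted(unknown)}")
        for fld in dataclasses.fields(cls):
            if fld.name in section and isinstance(section[fld.name], list):
                section[fld.name] = tuple(section[fld.name])
        kwargs[name] = cls(**section)
    return RunConfig(seed=int(raw.get("seed", 0)),
                     side=int(raw.get("side", 256)), **kwargs)
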