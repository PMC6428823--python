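"""Pipeline configuration: one structured object covering every stage,
serializable to/from YAML with strict (unknown-key-rejecting) loading."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields

import yaml

from .classify import SvmParams
from .enhancement import EnhanceParams
from .segmentation import DeParams, SegmentationParams
from .wld import WldConfig

__all__ = ["CandidateParams", "PipelineConfig", "load_config", "save_config"]


@dataclass
class CandidateParams:
    d_min_mm: float = 3.0
    d_max_mm: float = 30.0
    elong_max: float = 3.0
    k: int = 2


@dataclass
class PipelineConfig:
    enhancement: EnhanceParams = field(default_factory=EnhanceParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    candidates: CandidateParams = field(default_factory=CandidateParams)
    features: WldConfig = field(default_factory=WldConfig)
    classifier: SvmParams = field(default_factory=SvmParams)
    window_hu: tuple[float, float] = (-1000.0, 400.0)
    seed: int = 0
    verbosity: int = 0


def _to_dict(obj):
    if dataclasses.is_dataclass(obj):
        return {f.name: _to_dict(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def _from_dict(cls, data: dict):
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = known[name].type
        default = getattr(cls(), name) if dataclasses.is_dataclass(cls) else None
        if dataclasses.is_dataclass(default):
            kwargs[name] = _from_dict(type(default), value)
        elif isinstance(default, tuple) and isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
        del ftype
    return cls(**kwargs)


def save_config(config: PipelineConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_dict(config), fh, sort_keys=False)


def load_config(path: str) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _from_dict(PipelineConfig, data)
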