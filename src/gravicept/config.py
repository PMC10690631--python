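"""YAML configuration: override scene geometry, generative parameters and
sampler settings from a single file.

Recognised top-level blocks (all optional):

    scene:      any SceneGeometry field
    generative: any GenerativeParams field
    sampler:    any SamplerConfig field
    priors:     any PriorConfig field
    ks:         any KSParams field
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import yaml

from .bayes_inference import PriorConfig, SamplerConfig
from .predictors import KSParams
from .scene_kinematics import SceneGeometry
from .synthetic_data import GenerativeParams

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    scene: SceneGeometry = field(default_factory=SceneGeometry)
    generative: GenerativeParams = field(default_factory=GenerativeParams)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    priors: PriorConfig = field(default_factory=PriorConfig)
    ks: KSParams = field(default_factory=KSParams)


def _build(cls, block: dict | None):
    block = block or {}
    known = {f.name for f in fields(cls)}
    unknown = set(block) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} fields: {sorted(unknown)}")
    if cls is KSParams and "window" in block:
        block = dict(block, window=tuple(block["window"]))
    return cls(**block)


def load_config(path: str | None = None) -> RunConfig:
    """Load a RunConfig from YAML; ``None`` gives all defaults."""
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    return RunConfig(
        scene=_build(SceneGeometry, raw.get("scene")),
        generative=_build(GenerativeParams, raw.get("generative")),
        sampler=_build(SamplerConfig, raw.get("sampler")),
        priors=_build(PriorConfig, raw.get("priors")),
        ks=_build(KSParams, raw.get("ks")),
    )
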