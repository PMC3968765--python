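"""Pipeline configuration: strict YAML loading with validated stage blocks.

A config file names a stage (``simulate``, ``bootstrap``, ``itemwise``,
``glmm`` or ``cohort``) and provides that stage's parameter block plus a
global seed and output directory.  Unknown keys are rejected by name so
typos fail loudly before any computation starts.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

from .attenuation import AttenuationSpec
from .cohort import CohortSpec
from .glmm import GlmmSpec
from .traits import ConfigurationError, TraitSpec

__all__ = ["PipelineConfig", "load_config", "dump_config"]

STAGES = ("simulate", "bootstrap", "itemwise", "glmm", "cohort")

_STAGE_SPECS = {
    "simulate": TraitSpec,
    "bootstrap": AttenuationSpec,
    "glmm": GlmmSpec,
    "cohort": CohortSpec,
    "itemwise": None,
}


@dataclass
class PipelineConfig:
    """One validated stage configuration."""

    stage: str
    seed: int = 0
    out_dir: str = "."
    params: Any = None
    extra: dict = field(default_factory=dict)


def _build_spec(cls, block: dict, context: str):
    """Instantiate a spec dataclass from a dict, rejecting unknown keys."""
    allowed = {f.name for f in fields(cls)}
    unknown = set(block) - allowed
    if unknown:
        raise ConfigurationError(
            f"unknown key {sorted(unknown)[0]!r} in {context} block"
        )
    coerced = dict(block)
    for f in fields(cls):
        if f.name in coerced and isinstance(coerced[f.name], list):
            coerced[f.name] = tuple(coerced[f.name])
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"invalid {context} block: {exc}") from exc


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline config."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigurationError("config must be a mapping")
    top_allowed = {"stage", "seed", "out_dir", "params"}
    unknown = set(raw) - top_allowed
    if unknown:
        raise ConfigurationError(f"unknown top-level key {sorted(unknown)[0]!r}")
    stage = raw.get("stage")
    if stage not in STAGES:
        raise ConfigurationError(
            f"stage must be one of {STAGES}, got {stage!r}"
        )
    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        raise ConfigurationError("seed must be an integer")
    block = raw.get("params", {}) or {}
    cls = _STAGE_SPECS[stage]
    params = _build_spec(cls, block, stage) if cls is not None else dict(block)
    return PipelineConfig(
        stage=stage, seed=seed, out_dir=str(raw.get("out_dir", ".")), params=params
    )


def dump_config(cfg: PipelineConfig, path: str | Path) -> None:
    """Write a config back to YAML in normalized form (round-trip stable)."""
    def plain(v):
        if hasattr(v, "tolist"):
            return v.tolist()
        if isinstance(v, tuple):
            return list(v)
        return v

    if hasattr(cfg.params, "__dataclass_fields__"):
        block = {
            k: plain(v) for k, v in asdict(cfg.params).items() if v is not None
        }
    else:
        block = dict(cfg.params or {})
    doc = {"stage": cfg.stage, "seed": cfg.seed, "out_dir": cfg.out_dir, "params": block}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))
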