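"""Pipeline configuration: one YAML file holds every threshold and seed.

Unknown keys are rejected so a typo cannot silently fall back to a
default; each run writes the fully resolved config beside its outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .ace_core import DEFAULT_T_CLAMP, KernelSpec
from .preprocess import PreprocessConfig
from .significance import PermutationConfig, SegmentConfig
from .synthetic_data import CnaRegionSpec, SimulationConfig


class ConfigError(ValueError):
    pass


def _build(cls, block: dict[str, Any], where: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - names
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")
    try:
        return cls(**block)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {where} block: {exc}") from None


@dataclass
class ConsensusConfig:
    min_cohorts: int | None = None


@dataclass
class PipelineConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    kernel: KernelSpec = field(default_factory=KernelSpec)
    permutation: PermutationConfig = field(default_factory=PermutationConfig)
    segment: SegmentConfig = field(default_factory=SegmentConfig)
    consensus: ConsensusConfig = field(default_factory=ConsensusConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    t_clamp: float = DEFAULT_T_CLAMP
    seed: int = 0
    output_dir: str = "results"


_BLOCKS = {
    "preprocess": PreprocessConfig,
    "kernel": KernelSpec,
    "permutation": PermutationConfig,
    "segment": SegmentConfig,
    "consensus": ConsensusConfig,
}
_SCALARS = {"t_clamp", "seed", "output_dir"}


def load_config(path: str | Path | None) -> PipelineConfig:
    """Parse and validate a YAML config; None yields all defaults."""
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(raw) - set(_BLOCKS) - _SCALARS - {"simulation"}
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for name, cls in _BLOCKS.items():
        if name in raw:
            kwargs[name] = _build(cls, raw[name] or {}, name)
    if "simulation" in raw:
        sim = dict(raw["simulation"] or {})
        regions = sim.pop("cna_regions", [])
        sim["cna_regions"] = tuple(
            _build(CnaRegionSpec, r, "simulation.cna_regions") for r in regions
        )
        kwargs["simulation"] = _build(SimulationConfig, sim, "simulation")
    for name in _SCALARS:
        if name in raw:
            kwargs[name] = raw[name]
    return PipelineConfig(**kwargs)


def dump_config(cfg: PipelineConfig, path: str | Path) -> None:
    """Write the resolved configuration next to a run's outputs."""

    def encode(obj: Any) -> Any:
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (list, tuple)):
            return [encode(v) for v in obj]
        return obj

    with open(path, "w") as fh:
        yaml.safe_dump(encode(cfg), fh, sort_keys=False)
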