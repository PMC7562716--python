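"""Declarative pipeline configuration with strict YAML (de)serialization.

A single :class:`PipelineConfig` wires the whole workflow (mask -> patch ->
stain-normalize -> predict -> heatmap -> featurize -> classify).  Unknown
keys are rejected on load, and every pipeline run writes the resolved
config next to its outputs so runs are self-describing.  One global seed
fans out to per-stage seeds by stable hashing so stages never share a
random stream.
"""

from __future__ import annotations

import dataclasses
import hashlib
from pathlib import Path
from typing import Any, Mapping

import yaml

from .patch_model import ClassifierConfig
from .wsi_features import ForestConfig


@dataclasses.dataclass
class MaskParams:
    downsample: int = 32
    close_radius: int = 4
    min_area_fraction: float = 0.005


@dataclasses.dataclass
class StainStage:
    enabled: bool = True
    beta: float = 0.15
    alpha: float = 0.01
    brightness_percentile: float = 95.0


@dataclasses.dataclass
class PatchParams:
    training_scales: tuple[int, ...] = (768, 1024, 1495, 2048)
    stride_fraction: float = 1.0
    out_side: int = 299
    min_tissue_fraction: float = 0.5
    purity_threshold: float = 0.9


@dataclasses.dataclass
class HeatmapParams:
    cell_size: int = 1024
    min_tissue_fraction: float = 0.25


@dataclasses.dataclass
class SynthParams:
    """Synthetic input generation for self-contained demo runs."""

    n_slides: int = 18
    slide_size: int = 1024
    lesion_fraction: float = 0.45
    seed_offset: int = 0


#: Stages in canonical execution order.
PIPELINE_STAGES = (
    "synth", "mask", "patch", "train", "heatmap", "featurize", "classify"
)


@dataclasses.dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run."""

    workdir: str = "gastroslide-run"
    input_dir: str | None = None  # slides + ASAP XML; None => synthesize
    seed: int = 0
    stages: tuple[str, ...] = PIPELINE_STAGES
    splits: tuple[float, float, float] = (0.7, 0.2, 0.1)
    synth: SynthParams = dataclasses.field(default_factory=SynthParams)
    mask: MaskParams = dataclasses.field(default_factory=MaskParams)
    stain: StainStage = dataclasses.field(default_factory=StainStage)
    patch: PatchParams = dataclasses.field(default_factory=PatchParams)
    heatmap: HeatmapParams = dataclasses.field(default_factory=HeatmapParams)
    classifier: ClassifierConfig = dataclasses.field(default_factory=ClassifierConfig)
    forest: ForestConfig = dataclasses.field(default_factory=ForestConfig)

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in PIPELINE_STAGES]
        if unknown:
            raise ValueError(
                f"unknown stages {unknown}; valid stages are {PIPELINE_STAGES}"
            )


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a stable per-stage seed below 2**31 from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _from_mapping(cls, data: Mapping[str, Any]):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(
            f"unknown {cls.__name__} keys: {sorted(unknown)}; "
            f"accepted keys: {sorted(fields)}"
        )
    kwargs = {}
    for name, value in data.items():
        factory = fields[name].default_factory
        nested = (
            factory is not dataclasses.MISSING
            and dataclasses.is_dataclass(factory())
        )
        if nested:
            kwargs[name] = _from_mapping(type(factory()), value or {})
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj):
        return {
            f.name: _to_plain(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
        }
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    return obj


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML pipeline config; unknown keys raise."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    return _from_mapping(PipelineConfig, data)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(_to_plain(config), sort_keys=False)
    )
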