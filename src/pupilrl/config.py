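"""Pipeline configuration: strict (unknown keys rejected) YAML/JSON loading."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .hierfit import PriorConfig, SamplerConfig
from .preproc import IRFParams
from .synth import SynthSpec
from .task import EventTiming, PairSpec, TaskConfig

__all__ = [
    "PreprocConfig", "DeconvConfig", "StatsConfig", "CohortConfig",
    "ModelConfig", "SeedConfig", "PipelineConfig", "load_config",
]


def _strict(cls, data: dict, where: str):
    """Build a dataclass from a dict, rejecting unknown keys."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown keys in {where}: {sorted(unknown)}")
    return cls(**data)


@dataclass
class PreprocConfig:
    blink_margin: float = 0.2
    residual_blink_k: float = 6.0
    low_hz: float = 0.05
    high_hz: float = 4.0
    filter_order: int = 3
    target_fs: float = 20.0
    saccade_threshold: float = 3.3
    rt_floor: float = 0.15
    rt_deadline: float = 3.5
    irf: IRFParams = field(default_factory=IRFParams)


@dataclass
class DeconvConfig:
    n_splits: int = 20
    test_frac: float = 0.2
    lambda_grid_size: int = 21


@dataclass
class StatsConfig:
    n_perm: int = 1000
    n_boot: int = 10000
    alpha: float = 0.05
    amplitude_early: tuple[float, float] = (0.5, 1.5)
    amplitude_late: tuple[float, float] = (1.5, 3.0)


@dataclass
class CohortConfig:
    n_subjects: int = 34
    group_mu: tuple[float, float, float] = (0.0, -1.0, -1.5)
    group_delta: tuple[float, float, float] = (1.2, 1.2, 1.2)


@dataclass
class ModelConfig:
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    priors: PriorConfig = field(default_factory=PriorConfig)
    variant: str = "two_alpha"
    n_sim_reps: int = 100


@dataclass
class SeedConfig:
    simulate: int = 1
    fit: int = 2
    preprocess: int = 3
    deconvolve: int = 4
    stats: int = 5


@dataclass
class PipelineConfig:
    task: TaskConfig = field(default_factory=TaskConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    deconv: DeconvConfig = field(default_factory=DeconvConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    synth: SynthSpec = field(default_factory=SynthSpec)
    seeds: SeedConfig = field(default_factory=SeedConfig)

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: enc(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
            if isinstance(obj, (list, tuple)):
                return [enc(x) for x in obj]
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            return obj

        return enc(self)

    def digest(self) -> str:
        import hashlib

        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def _build_task(data: dict) -> TaskConfig:
    data = dict(data)
    if "pairs" in data:
        data["pairs"] = [PairSpec(*p) for p in data["pairs"]]
    if "transfer_pairs" in data:
        data["transfer_pairs"] = [tuple(p) for p in data["transfer_pairs"]]
    if "timing" in data:
        data["timing"] = _strict(EventTiming, data["timing"], "task.timing")
    return _strict(TaskConfig, data, "task")


def _build_model(data: dict) -> ModelConfig:
    data = dict(data)
    if "sampler" in data:
        data["sampler"] = _strict(SamplerConfig, data["sampler"], "model.sampler")
    if "priors" in data:
        data["priors"] = _strict(PriorConfig, data["priors"], "model.priors")
    return _strict(ModelConfig, data, "model")


def _build_synth(data: dict) -> SynthSpec:
    data = dict(data)
    if "irf" in data:
        data["irf"] = _strict(IRFParams, data["irf"], "synth.irf")
    return _strict(SynthSpec, data, "synth")


def _build_preproc(data: dict) -> PreprocConfig:
    data = dict(data)
    if "irf" in data:
        data["irf"] = _strict(IRFParams, data["irf"], "preproc.irf")
    return _strict(PreprocConfig, data, "preproc")


def load_config(source: str | Path | dict | None = None) -> PipelineConfig:
    """Load a pipeline config from a YAML/JSON file or a nested dict.

    Unknown keys at any level raise with a field-level message.
    """
    if source is None:
        return PipelineConfig()
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
    else:
        data = dict(source)

    builders = {
        "task": _build_task,
        "cohort": lambda d: _build_cohort(d),
        "model": _build_model,
        "preproc": _build_preproc,
        "deconv": lambda d: _strict(DeconvConfig, d, "deconv"),
        "stats": lambda d: _build_stats(d),
        "synth": _build_synth,
        "seeds": lambda d: _strict(SeedConfig, d, "seeds"),
    }
    unknown = set(data) - set(builders)
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    kwargs = {key: builders[key](val) for key, val in data.items()}
    return PipelineConfig(**kwargs)


def _build_cohort(d: dict) -> CohortConfig:
    d = dict(d)
    for key in ("group_mu", "group_delta"):
        if key in d:
            d[key] = tuple(d[key])
    return _strict(CohortConfig, d, "cohort")


def _build_stats(d: dict) -> StatsConfig:
    d = dict(d)
    for key in ("amplitude_early", "amplitude_late"):
        if key in d:
            d[key] = tuple(d[key])
    return _strict(StatsConfig, d, "stats")
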