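"""Pipeline configuration: validated, nested, loadable from YAML/JSON."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .features import WindowSpec
from .preprocess import FilterSpec

__all__ = ["PipelineConfig", "StftConfig", "WaveletConfig", "ClusterConfig",
           "TsvmConfig", "EvalConfig", "SamplingConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


@dataclass(frozen=True)
class SamplingConfig:
    fs: float = 1024.0

    def __post_init__(self):
        if self.fs <= 0:
            raise ConfigError("sampling.fs must be positive")


@dataclass(frozen=True)
class StftConfig:
    window_len: int = 256
    overlap: float = 0.5

    def __post_init__(self):
        if self.window_len < 8 or self.window_len % 2:
            raise ConfigError("stft.window_len must be an even integer >= 8")
        if self.overlap != 0.5:
            raise ConfigError("stft.overlap: only 50% overlap is supported "
                              "(exact overlap-add reconstruction)")


@dataclass(frozen=True)
class WaveletConfig:
    name: str = "bior3.3"
    n_scales: int = 4
    signed_maxima: bool = False

    def __post_init__(self):
        if self.n_scales < 2:
            raise ConfigError("wavelet.n_scales must be >= 2")


@dataclass(frozen=True)
class ClusterConfig:
    """``mode="flexion"`` estimates the k magnitude levels from the whole
    flexion and counts per window (stable cluster ranks); ``"window"``
    re-clusters every window independently."""

    k: int = 4
    mode: str = "flexion"

    def __post_init__(self):
        if self.k < 1:
            raise ConfigError("clustering.k must be >= 1")
        if self.mode not in ("flexion", "window"):
            raise ConfigError("clustering.mode must be 'flexion' or 'window'")


@dataclass(frozen=True)
class TsvmConfig:
    c1: float = 1.0
    c2: float = 1.0
    eps: float = 1e-6

    def __post_init__(self):
        if self.c1 <= 0 or self.c2 <= 0 or self.eps <= 0:
            raise ConfigError("tsvm parameters c1, c2, eps must be positive")


@dataclass(frozen=True)
class EvalConfig:
    mode: str = "subsample"
    n_train: int = 100
    n_test: int = 30
    n_folds: int = 10
    n_repetitions: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("subsample", "kfold"):
            raise ConfigError("eval.mode must be 'subsample' or 'kfold'")
        if min(self.n_train, self.n_test, self.n_folds, self.n_repetitions) < 1:
            raise ConfigError("eval counts must be positive")


@dataclass(frozen=True)
class PipelineConfig:
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    filter: FilterSpec = field(default_factory=FilterSpec)
    stft: StftConfig = field(default_factory=StftConfig)
    wavelet: WaveletConfig = field(default_factory=WaveletConfig)
    window: WindowSpec = field(default_factory=WindowSpec)
    clustering: ClusterConfig = field(default_factory=ClusterConfig)
    tsvm: TsvmConfig = field(default_factory=TsvmConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)
    oversubtraction_alpha: float = 1.0
    per_window_features: bool = True

    def __post_init__(self):
        if self.oversubtraction_alpha < 0:
            raise ConfigError("oversubtraction_alpha must be >= 0")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return _build(cls, d, "config")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _build(cls, d: dict, where: str):
    """Recursively build a dataclass from a dict, rejecting unknown keys."""
    if not isinstance(d, dict):
        raise ConfigError(f"{where}: expected a mapping, got {type(d).__name__}")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(d) - set(fields)
    if unknown:
        raise ConfigError(f"{where}: unknown keys {sorted(unknown)}; "
                          f"allowed keys are {sorted(fields)}")
    kwargs = {}
    for name, value in d.items():
        ftype = fields[name].type
        target = _nested_types().get((cls.__name__, name))
        if target is not None:
            kwargs[name] = _build(target, value, f"{where}.{name}")
        else:
            kwargs[name] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{where}: {exc}") from exc


def _nested_types():
    return {
        ("PipelineConfig", "sampling"): SamplingConfig,
        ("PipelineConfig", "filter"): FilterSpec,
        ("PipelineConfig", "stft"): StftConfig,
        ("PipelineConfig", "wavelet"): WaveletConfig,
        ("PipelineConfig", "window"): WindowSpec,
        ("PipelineConfig", "clustering"): ClusterConfig,
        ("PipelineConfig", "tsvm"): TsvmConfig,
        ("PipelineConfig", "eval"): EvalConfig,
    }
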