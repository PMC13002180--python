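"""Structured run configuration.

One YAML/JSON file with sections mirroring the pipeline stages.  Unknown
keys are rejected with the offending key named.  Defaults follow the
standard setup: 10 µV recording noise, 50 µV degradation noise, 30 kHz,
300–3,000 Hz order-5 causal bandpass, MT radius 75 µm / window 1,000 µm,
GC radius 40 µm / 5 µm grid / top 5%, and 30 µm (simulated) or 50 µm
(experimental) accuracy radii.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "SimulateConfig",
    "PreprocessConfig",
    "LocalizeConfig",
    "BenchmarkConfig",
    "RunConfig",
    "ConfigError",
    "load_config",
    "desk_preset",
    "paper_preset",
]


class ConfigError(ValueError):
    """Malformed configuration (unknown key, bad type, bad value)."""


@dataclass
class SimulateConfig:
    n_channels: int = 384
    pitch_plan: dict | None = None
    n_neurons: int = 50
    duration_s: float = 90.0
    rate_hz: float = 5.0
    refractory_ms: float = 2.0
    noise_std: float = 10.0
    sampling_rate: float = 30000.0
    amp_modulation_cv: float = 0.05
    decay_exponent: float = 1.0
    z_range_um: list = field(default_factory=lambda: [10.0, 60.0])
    amplitude_median_uv: float = 100.0


@dataclass
class PreprocessConfig:
    low_hz: float = 300.0
    high_hz: float = 3000.0
    order: int = 5
    coherence_threshold: float = 0.2
    n_neighbors: int = 4
    psd_z_threshold: float = 4.0
    # which channels localizers treat as absent: none (dead channels stay
    # in the analysis, as in the degradation benchmark), the declared-dead
    # plan, the detector output, or their union
    channel_exclusion: str = "none"


@dataclass
class LocalizeConfig:
    com_radius_um: float = 75.0
    mt_radius_um: float = 75.0
    mt_max_distance_um: float = 1000.0
    gc_radius_um: float = 40.0
    gc_resolution_um: float = 5.0
    gc_percentile_top: float = 5.0
    gc_sigma_um: list = field(default_factory=lambda: [20.0])
    gc_z_max_um: float = 100.0


@dataclass
class BenchmarkConfig:
    levels: list = field(default_factory=lambda: [round(f, 4) for f in _linspace(0.0, 0.94, 25)])
    seeds: list = field(default_factory=lambda: [0, 1, 2, 3, 4])
    algorithms: list = field(default_factory=lambda: ["com", "mt", "gc"])
    accuracy_radius_um: float = 30.0
    degrade_noise_std: float = 50.0
    max_spikes_per_unit: int | None = None
    localize_spikes: bool = True
    pre_ms: float = 1.0
    post_ms: float = 2.0
    max_jitter_ms: float = 0.5


def _linspace(lo: float, hi: float, n: int) -> list[float]:
    if n == 1:
        return [lo]
    return [lo + (hi - lo) * i / (n - 1) for i in range(n)]


@dataclass
class RunConfig:
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    localize: LocalizeConfig = field(default_factory=LocalizeConfig)
    benchmark: BenchmarkConfig = field(default_factory=BenchmarkConfig)
    seed: int = 0
    output_dir: str = "results"


_SECTIONS = {
    "simulate": SimulateConfig,
    "preprocess": PreprocessConfig,
    "localize": LocalizeConfig,
    "benchmark": BenchmarkConfig,
}


def _build_section(cls, data: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    for key in data:
        if key not in known:
            raise ConfigError(f"unknown key {section}.{key}")
    return cls(**data)


def from_dict(data: dict) -> RunConfig:
    """Build a RunConfig from a nested dict, rejecting unknown keys."""
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    top_known = set(_SECTIONS) | {"seed", "output_dir"}
    for key in data:
        if key not in top_known:
            raise ConfigError(f"unknown key {key!r}")
    kwargs = {}
    for section, cls in _SECTIONS.items():
        raw = data.get(section, {})
        if not isinstance(raw, dict):
            raise ConfigError(f"section {section!r} must be a mapping")
        kwargs[section] = _build_section(cls, raw, section)
    cfg = RunConfig(
        seed=int(data.get("seed", 0)),
        output_dir=str(data.get("output_dir", "results")),
        **kwargs,
    )
    _validate(cfg)
    return cfg


def _validate(cfg: RunConfig) -> None:
    if cfg.simulate.n_channels < 4:
        raise ConfigError("simulate.n_channels must be >= 4")
    if cfg.simulate.sampling_rate <= 0:
        raise ConfigError("simulate.sampling_rate must be positive")
    if cfg.preprocess.high_hz >= cfg.simulate.sampling_rate / 2:
        raise ConfigError("preprocess.high_hz must be below Nyquist")
    for lv in cfg.benchmark.levels:
        if not 0.0 <= lv <= 1.0:
            raise ConfigError(f"benchmark.levels entry {lv} outside [0, 1]")
    for algo in cfg.benchmark.algorithms:
        if algo not in ("com", "mt", "gc"):
            raise ConfigError(f"unknown algorithm {algo!r} in benchmark.algorithms")
    if cfg.preprocess.channel_exclusion not in ("plan", "detected", "union", "none"):
        raise ConfigError(
            f"unknown preprocess.channel_exclusion {cfg.preprocess.channel_exclusion!r}"
        )
    if not math.isfinite(cfg.localize.gc_resolution_um) or cfg.localize.gc_resolution_um <= 0:
        raise ConfigError("localize.gc_resolution_um must be positive")


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML (or JSON) config file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if data is None:
        data = {}
    return from_dict(data)


def paper_preset() -> RunConfig:
    """Full-scale setup: 384 channels, 50 neurons, 90 s, 25 degradation
    levels from 0 to 94%, five seeds."""
    return RunConfig()


def desk_preset(seeds: list | None = None, levels: list | None = None) -> RunConfig:
    """Scaled-down setup for tests and laptops: 96 channels, 10 neurons,
    30 s, 5 levels, 3 seeds, 50 spikes per unit."""
    cfg = RunConfig()
    cfg.simulate.n_channels = 96
    cfg.simulate.n_neurons = 10
    cfg.simulate.duration_s = 30.0
    cfg.benchmark.levels = [0.0, 0.25, 0.5, 0.75, 0.9] if levels is None else list(levels)
    cfg.benchmark.seeds = [0, 1, 2] if seeds is None else list(seeds)
    cfg.benchmark.max_spikes_per_unit = 50
    # 30 s gives ~150-spike templates vs ~450 at full scale; scale the
    # source amplitude so the template signal-to-noise-floor ratio stays
    # comparable to the full-length setting (floor ~ 1/sqrt(n_spikes))
    cfg.simulate.amplitude_median_uv = 150.0
    return cfg


def to_dict(cfg: RunConfig) -> dict:
    return dataclasses.asdict(cfg)
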