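"""Single-file pipeline configuration.

A YAML document with one section per stage; unknown keys are rejected and
every field defaults to the printed study value where one exists.  CLI
flags override individual fields.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .features import WindowSpec
from .simulate import SimulationConfig
from .twin import ElderConfig, YoungerConfig


@dataclass
class LabelingConfig:
    threshold_k: float = 0.2
    debounce_ms: float = 20.0
    on_double_off: str = "impute"
    per_cycle_percentage: bool = False


@dataclass
class EvaluationConfig:
    split: str = "holdout"        # {"holdout", "kfold"}
    test_fraction: float = 0.3    # the 7:3 protocol
    n_folds: int = 10
    baselines: tuple = ()         # e.g. ("svm", "knn")

    def __post_init__(self) -> None:
        if self.split not in ("holdout", "kfold"):
            raise ValueError(f"unknown split mode {self.split!r}")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "lateralgait_run"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    windowing: WindowSpec = field(default_factory=WindowSpec)
    labeling: LabelingConfig = field(default_factory=LabelingConfig)
    elder: ElderConfig = field(default_factory=ElderConfig)
    younger: YoungerConfig = field(default_factory=YoungerConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be a nonnegative integer")


_SECTIONS = {
    "simulation": SimulationConfig,
    "windowing": WindowSpec,
    "labeling": LabelingConfig,
    "elder": ElderConfig,
    "younger": YoungerConfig,
    "evaluation": EvaluationConfig,
}

_LIST_FIELDS = {"phase_fractions", "burst_centers", "kernel", "hidden",
                "baselines"}


def _build_section(cls, data: dict, section: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown key(s) in section '{section}': "
                         f"{sorted(unknown)}")
    kwargs = {}
    for k, v in data.items():
        if k == "activation_matrix":
            v = np.asarray(v, float)
        elif k in _LIST_FIELDS and isinstance(v, list):
            v = tuple(v)
        kwargs[k] = v
    return cls(**kwargs)


def validate_config(raw_text: str) -> PipelineConfig:
    """Parse YAML text into a fully defaulted, validated PipelineConfig."""
    data = yaml.safe_load(raw_text) or {}
    if not isinstance(data, dict):
        raise ValueError("configuration must be a YAML mapping")
    top_fields = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - top_fields
    if unknown:
        raise ValueError(f"unknown top-level key(s): {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in data:
            section = data[name]
            if not isinstance(section, dict):
                raise ValueError(f"section '{name}' must be a mapping")
            kwargs[name] = _build_section(cls, section, name)
    for scalar in ("seed", "out_dir"):
        if scalar in data:
            kwargs[scalar] = data[scalar]
    cfg = PipelineConfig(**kwargs)
    # a single global seed propagates unless a stage pins its own
    sim = data.get("simulation", {})
    if "seed" not in sim:
        cfg.simulation.seed = cfg.seed
    if "seed" not in data.get("elder", {}):
        cfg.elder.seed = cfg.seed
    if "seed" not in data.get("younger", {}):
        cfg.younger.seed = cfg.seed
    return cfg


def load_config(path: str | Path | None) -> PipelineConfig:
    if path is None:
        return validate_config("")
    return validate_config(Path(path).read_text())


def config_to_dict(cfg: PipelineConfig) -> dict:
    def conv(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, tuple):
            return list(obj)
        if dataclasses.is_dataclass(obj):
            return {k: conv(v) for k, v in obj.__dict__.items()}
        return obj

    return conv(cfg)
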