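"""Experiment configuration: one YAML file drives the whole pipeline.

Every random operation derives its seed deterministically from the single
global ``seed``, so a finished experiment can be reproduced from its config
alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .core import VMI_LEVELS


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass
class PhantomSection:
    n_cases: int = 10
    grid_shape: tuple[int, int, int] = (64, 64, 32)
    grid_spacing: tuple[float, float, float] = (3.0, 3.0, 4.0)
    geometry: dict = field(default_factory=dict)   # PhantomGeometry overrides
    spectral: dict = field(default_factory=dict)   # SpectralModel overrides


@dataclass
class ModelSection:
    backbone: str = "unetpp"
    variant: str = "aug"
    widths: tuple[int, ...] | None = None


@dataclass
class TrainingSection:
    epochs: int = 10
    batch_size: int = 8
    learning_rate: float = 1e-3
    n_folds: int = 3
    k_slices: int = 3
    baseline_level: int = 70
    window: tuple[float, float] = (0.0, 100.0)
    levels: tuple[int, ...] = VMI_LEVELS


@dataclass
class EvaluationSection:
    test_fraction: float = 0.2   # 4:1 train:test split


@dataclass
class RunConfig:
    """Full experiment description; ``seed`` and ``out_root`` are required."""

    seed: int
    out_root: str
    phantom: PhantomSection = field(default_factory=PhantomSection)
    model: ModelSection = field(default_factory=ModelSection)
    training: TrainingSection = field(default_factory=TrainingSection)
    evaluation: EvaluationSection = field(default_factory=EvaluationSection)

    def __post_init__(self) -> None:
        if not 0.0 < self.evaluation.test_fraction < 1.0:
            raise ConfigError("evaluation.test_fraction must be in (0, 1)")
        if self.phantom.n_cases < 2:
            raise ConfigError("phantom.n_cases must be >= 2 (need a test case)")

    # -- (de)serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            return obj

        return plain(asdict(self))

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        payload = dict(payload)
        for name in ("seed", "out_root"):
            if name not in payload:
                raise ConfigError(f"missing required field {name!r}")
        sections = {
            "phantom": PhantomSection, "model": ModelSection,
            "training": TrainingSection, "evaluation": EvaluationSection,
        }
        kwargs: dict = {"seed": int(payload.pop("seed")),
                        "out_root": str(payload.pop("out_root"))}
        for name, section_cls in sections.items():
            sub = payload.pop(name, {})
            if not isinstance(sub, dict):
                raise ConfigError(f"section {name!r} must be a mapping")
            known = {f.name for f in section_cls.__dataclass_fields__.values()}
            unknown = set(sub) - known
            if unknown:
                raise ConfigError(f"unknown fields in section {name!r}: {sorted(unknown)}")
            coerced = {k: tuple(v) if isinstance(v, list) else v for k, v in sub.items()}
            kwargs[name] = section_cls(**coerced)
        if payload:
            raise ConfigError(f"unknown top-level fields: {sorted(payload)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        payload = yaml.safe_load(path.read_text())
        if not isinstance(payload, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        return cls.from_dict(payload)
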