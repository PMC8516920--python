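"""Run configuration: nested, validated, YAML round-trippable."""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field

import yaml

from .networks import ModelConfig, default_disc_layers, reduced_disc_layers
from .phantom import PhantomSpec
from .training import TrainingConfig

_DISC_PRESETS = {"default": default_disc_layers, "reduced": reduced_disc_layers}


def derive_seed(global_seed: int, stage: str) -> int:
    """Fan a single run seed out to a stable per-stage seed (< 2**31)."""
    return (int(global_seed) * 2654435761 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    """Everything needed to run simulate -> train -> infer -> evaluate."""

    seed: int = 0
    out_dir: str = "runs/out"
    n_train_pairs: int = 16
    n_eval_pairs: int = 4
    disc_preset: str = "default"
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    model: ModelConfig = field(default_factory=ModelConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)

    def __post_init__(self) -> None:
        if self.n_train_pairs < 1 or self.n_eval_pairs < 0:
            raise ValueError("need >= 1 training pair and >= 0 evaluation pairs")
        if self.disc_preset not in _DISC_PRESETS:
            raise ValueError(f"unknown disc_preset {self.disc_preset!r}")


def _section_to_dict(obj) -> dict:
    out = {}
    for f in dataclasses.fields(obj):
        if f.name == "disc_layers":
            continue  # carried by disc_preset
        v = getattr(obj, f.name)
        out[f.name] = list(v) if isinstance(v, tuple) else v
    return out


def _dict_to_section(cls, data: dict, extra: dict | None = None):
    allowed = {f.name for f in dataclasses.fields(cls)} - {"disc_layers"}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {cls.__name__} section: {sorted(unknown)}")
    kwargs = {
        k: tuple(v) if isinstance(v, list) else v for k, v in data.items()
    }
    if extra:
        kwargs.update(extra)
    return cls(**kwargs)


def config_to_dict(config: RunConfig) -> dict:
    return {
        "seed": config.seed,
        "out_dir": config.out_dir,
        "n_train_pairs": config.n_train_pairs,
        "n_eval_pairs": config.n_eval_pairs,
        "disc_preset": config.disc_preset,
        "phantom": _section_to_dict(config.phantom),
        "model": _section_to_dict(config.model),
        "training": _section_to_dict(config.training),
    }


def config_from_dict(data: dict) -> RunConfig:
    data = dict(data)
    known_top = {"seed", "out_dir", "n_train_pairs", "n_eval_pairs",
                 "disc_preset", "phantom", "model", "training"}
    unknown = set(data) - known_top
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    preset = data.get("disc_preset", "default")
    if preset not in _DISC_PRESETS:
        raise ValueError(f"unknown disc_preset {preset!r}")
    return RunConfig(
        seed=int(data.get("seed", 0)),
        out_dir=str(data.get("out_dir", "runs/out")),
        n_train_pairs=int(data.get("n_train_pairs", 16)),
        n_eval_pairs=int(data.get("n_eval_pairs", 4)),
        disc_preset=preset,
        phantom=_dict_to_section(PhantomSpec, data.get("phantom", {})),
        model=_dict_to_section(
            ModelConfig, data.get("model", {}),
            extra={"disc_layers": _DISC_PRESETS[preset]()}),
        training=_dict_to_section(TrainingConfig, data.get("training", {})),
    )


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh) or {})


def dump_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)
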