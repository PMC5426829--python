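"""Run configuration: YAML in, validated dataclasses out.

A RunConfig bundles the scene generator, network, trainer and baseline
settings plus output paths, so a whole generate -> train -> evaluate ->
compare run is reproducible from one file and one seed.  Unknown keys
are rejected rather than ignored.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .baselines import AreaBaselineConfig
from .synthgen import SceneConfig
from .trainer import TrainConfig


@dataclass
class NetworkConfig:
    width_multiplier: float = 1.0
    input_size: int = 128

    def __post_init__(self) -> None:
        if self.width_multiplier <= 0:
            raise ValueError("network.width_multiplier must be > 0")
        if self.input_size < 32:
            raise ValueError("network.input_size must be >= 32")


@dataclass
class RunConfig:
    scene: SceneConfig = field(default_factory=SceneConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    baseline: AreaBaselineConfig = field(default_factory=AreaBaselineConfig)
    n_train: int = 24000
    n_test: int = 2400
    out_dir: str = "runs/deepcount"
    log_level: str = "INFO"
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


# the full-scale profile is the default; `smoke` finishes in minutes
PROFILES = {
    "paper": {},
    "smoke": {
        "scene": {"image_size": 32, "fruit_count_range": [1, 10]},
        "network": {"width_multiplier": 0.25, "input_size": 32},
        "train": {"batch_size": 32},
        "n_train": 200,
        "n_test": 50,
    },
}


def _build(cls, data: dict, path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in fields:
            raise ValueError(f"unknown config key {path}{key}")
        ftype = fields[key].type
        sub = {"scene": SceneConfig, "train": TrainConfig,
               "network": NetworkConfig, "baseline": AreaBaselineConfig}.get(key)
        if sub is not None and isinstance(value, dict):
            kwargs[key] = _build(sub, value, f"{path}{key}.")
        elif isinstance(value, list):
            kwargs[key] = tuple(tuple(v) if isinstance(v, list) else v
                                for v in value)
        else:
            kwargs[key] = value
    try:
        return cls(**kwargs)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"invalid config under {path or 'top level'}: {exc}") \
            from exc


def load_config(path: str | Path | None = None,
                profile: str | None = None) -> RunConfig:
    """Parse and validate a YAML run config; an empty file (or no file)
    yields all defaults.  ``profile`` applies a bundled preset first."""
    data: dict = {}
    if profile is not None:
        if profile not in PROFILES:
            raise ValueError(f"unknown profile {profile!r}; "
                             f"choose from {sorted(PROFILES)}")
        data = yaml.safe_load(yaml.safe_dump(PROFILES[profile])) or {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError("config file must contain a YAML mapping")
        for key, value in loaded.items():
            if isinstance(value, dict) and isinstance(data.get(key), dict):
                data[key].update(value)
            else:
                data[key] = value
    return _build(RunConfig, data, "")


def dump_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
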