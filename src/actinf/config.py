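"""Run configuration: YAML-backed, validated, defaulted to the printed
settings of the two demonstrations (mountain car and saccadic search).

An empty config file yields the canonical setup: a 32 x 32 state grid over
position [-2, 2] x velocity [-3, 3] with 5 control levels and T = 16 steps of
8 variational sweeps each for the mountain car; a 16 x 16 retina, 32 x 32
salience grid, and 8 saccades of 16 x 12 ms bins for the visual search.
Unknown keys are rejected with their full key path.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


@dataclass
class MountainCarConfig:
    n_pos: int = 32
    pos_range: tuple[float, float] = (-2.0, 2.0)
    n_vel: int = 32
    vel_range: tuple[float, float] = (-3.0, 3.0)
    control_values: tuple[float, ...] = (-2.0, -1.0, 0.0, 1.0, 2.0)
    dt: float = 2.0
    T: int = 16
    sweeps_per_step: int = 8
    smoothing_sigma: float = 1.0
    scale: float = 0.15
    friction: float = 0.06
    n_substeps: int = 40
    goal: tuple[float, float] = (1.0, 0.0)
    start: tuple[float, float] = (0.0, 0.0)
    mode: str = "modal"


@dataclass
class SaccadeConfig:
    n_saccades: int = 8
    bins_per_saccade: int = 16
    dt_ms: float = 12.0
    retina_n_side: int = 16
    salience_grid: int = 32
    n_orders: int = 3
    perceptual_decay: float = 1.0 / 1024.0
    glyph_size: int = 128
    scene_index: int = 0
    noise: bool = True


@dataclass
class ToyMDPConfig:
    n_states: int = 4
    n_actions: int = 3
    horizon: int = 3
    determinism: float = 0.9
    n_sweeps: int = 16


@dataclass
class RunConfig:
    experiment: str = "mountain_car"
    seed: int = 0
    out_dir: str = "runs"
    log_level: str = "INFO"
    mountain_car: MountainCarConfig = field(default_factory=MountainCarConfig)
    saccade: SaccadeConfig = field(default_factory=SaccadeConfig)
    toy_mdp: ToyMDPConfig = field(default_factory=ToyMDPConfig)

    def __post_init__(self) -> None:
        if self.experiment not in ("mountain_car", "saccade", "toy_mdp"):
            raise ValueError(f"unknown experiment {self.experiment!r}")
        if self.mountain_car.mode not in ("modal", "sampled"):
            raise ValueError("mountain_car.mode must be 'modal' or 'sampled'")


def _build(cls: type, data: dict[str, Any], path: str) -> Any:
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs: dict[str, Any] = {}
    for key, val in data.items():
        if key not in fields:
            raise ValueError(f"unknown config key: {path}{key}")
        ftype = fields[key].type
        if isinstance(val, dict):
            sub = fields[key].default_factory  # type: ignore[union-attr]
            if sub is dataclasses.MISSING:
                raise ValueError(f"config key {path}{key} cannot be a mapping")
            kwargs[key] = _build(sub, val, f"{path}{key}.")
        elif isinstance(val, list):
            kwargs[key] = tuple(val)
        else:
            kwargs[key] = val
    return cls(**kwargs)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML config; ``None`` or an empty file gives the
    printed defaults.  Schema violations name the offending key path."""
    if path is None:
        return RunConfig()
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"config file not found: {p}")
    data = yaml.safe_load(p.read_text())
    if data is None:
        return RunConfig()
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    return _build(RunConfig, data, "")


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    """Write the fully resolved configuration as YAML."""
    def _plain(obj: Any) -> Any:
        if dataclasses.is_dataclass(obj):
            return {f.name: _plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, tuple):
            return [_plain(v) for v in obj]
        return obj

    Path(path).write_text(yaml.safe_dump(_plain(cfg), sort_keys=False))
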