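"""Structured run configuration (YAML) with strict validation.

Defaults follow the recommended settings: screening threshold alpha = 0.001,
K = 20 cross-validation folds, 100 permutations per fold, per-gene networks of
two hidden layers (50, 10) with dropout 0.5 and 100 training epochs, and a
stacked head of (100, 10) hidden nodes. Unknown keys are rejected so typos
fail loudly; a parsed config round-trips through :func:`write_config`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .screening import NetworkConfig
from .transfer import TransferConfig

__all__ = ["RunConfig", "ScreeningConfig", "parse_config", "write_config", "config_to_dict"]


@dataclass(frozen=True)
class ScreeningConfig:
    alpha: float = 0.001
    k_folds: int = 20
    n_perm: int = 100
    network: NetworkConfig = field(default_factory=NetworkConfig)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"screening.alpha must be in (0, 1], got {self.alpha}")
        if self.k_folds < 2:
            raise ValueError("screening.k_folds must be >= 2")
        if self.n_perm < 1:
            raise ValueError("screening.n_perm must be >= 1")


@dataclass(frozen=True)
class RunConfig:
    geno: str | None = None
    pheno: str | None = None
    regions: str | None = None
    out: str | None = None
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    transfer: TransferConfig = field(default_factory=TransferConfig)
    test_fraction: float = 0.25
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")


def _from_dict(cls, data: dict, path: str = ""):
    if not isinstance(data, dict):
        raise ValueError(f"config section {path or '<root>'} must be a mapping")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"unknown config key(s) {sorted(unknown)} in section {path or '<root>'}")
    kwargs = {}
    for name, value in data.items():
        ftype = fields[name].type
        sub = {"screening": ScreeningConfig, "transfer": TransferConfig, "network": NetworkConfig}
        if name in sub and isinstance(value, dict):
            kwargs[name] = _from_dict(sub[name], value, f"{path}{name}.")
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid config in section {path or '<root>'}: {exc}") from exc


def config_to_dict(cfg) -> dict:
    def clean(obj):
        if dataclasses.is_dataclass(obj):
            return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, tuple):
            return list(obj)
        return obj

    return clean(cfg)


def parse_config(path: str | Path) -> RunConfig:
    """Parse a YAML config file; an empty file yields all defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _from_dict(RunConfig, data)


def write_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)
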