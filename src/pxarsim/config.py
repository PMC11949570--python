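"""Run configuration files (YAML) for the command-line interface.

A config describes one experiment: the kind (point-pattern, GLV, or a
measurement-only pass over an existing point snapshot), the parameter
grid or single parameter set, replicate count, master seed and variant
flags.  Unknown keys are rejected so that typos fail loudly, and a
loaded config round-trips losslessly back to YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

__all__ = ["RunConfig", "load_config", "ConfigError"]

CONFIG_VERSION = 1

_KINDS = ("pp", "lv", "measure")
_ALLOWED = {
    "version", "kind", "grid", "params", "replicates", "master_seed",
    "variant", "px_mode", "sd_exponent_mode", "levels", "workers", "scaled",
}
_REQUIRED = {"kind"}


class ConfigError(ValueError):
    """Malformed run configuration; message names the offending key."""


@dataclass
class RunConfig:
    kind: str
    grid: list | None = None
    params: dict | None = None
    replicates: int = 10
    master_seed: int = 0
    variant: str = "shared"
    px_mode: str = "ratio_of_means"
    sd_exponent_mode: str = "taylor"
    levels: list = field(default_factory=lambda: [2, 4, 8, 16])
    workers: int = 1
    scaled: bool = False
    version: int = CONFIG_VERSION

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ConfigError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        if self.version != CONFIG_VERSION:
            raise ConfigError(f"unsupported config version {self.version!r}")

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        if not isinstance(raw, dict):
            raise ConfigError("config must be a mapping")
        unknown = set(raw) - _ALLOWED
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        missing = _REQUIRED - set(raw)
        if missing:
            raise ConfigError(f"missing required config key(s): {sorted(missing)}")
        return cls(**raw)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig.from_dict(raw)
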