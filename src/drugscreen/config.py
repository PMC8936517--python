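"""Run configuration: defaults, plain-text (YAML ``key: value``) files, and
flag overrides with precedence flags > file > defaults."""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path
from typing import Optional

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    inputs: list[str] = field(default_factory=list)
    outdir: str = "results"
    dss_threshold: float = 10.0      # activity threshold t, % inhibition
    dss_grid_n: int = 1024
    zprime_floor: float = 0.4
    force_normalize: bool = False    # analyze plates failing QC anyway
    replicate_rule: bool = True
    residual_rule: bool = True
    synergy_monotherapy_source: str = "zero_dose_cells"
    cluster_k: Optional[int] = None
    z_score: bool = False
    seed: int = 0

    def validate(self) -> "RunConfig":
        if not 0 <= self.dss_threshold < 100:
            raise ConfigError("dss_threshold must lie in [0, 100)")
        if self.dss_grid_n < 256:
            raise ConfigError("dss_grid_n must be >= 256")
        if self.synergy_monotherapy_source not in ("zero_dose_cells",
                                                   "external_curves"):
            raise ConfigError("synergy_monotherapy_source must be "
                              "'zero_dose_cells' or 'external_curves'")
        return self


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Defaults, optionally updated from a YAML file, then from overrides.

    Unknown keys are rejected by name.
    """
    known = {f.name for f in fields(RunConfig)}
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: config must be a key: value mapping")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})
    unknown = sorted(set(data) - known)
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(unknown)}")
    return RunConfig(**data).validate()


def dump_config(config: RunConfig, path: str | Path) -> None:
    """Echo the effective configuration verbatim into the run directory."""
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=True))
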