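"""Run configuration: schema-checked options, JSON/YAML loading, hashing.

Every CLI artifact embeds ``config_hash(cfg)`` and the master seed so a
run can be reproduced exactly from its outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    # cross-validated model
    k_features: int = 10
    threshold: float = 0.5
    db_scatter_exponent: int = 1
    # permutation test
    permutations: int = 100
    seed: int = 0
    beta_shape: str = "laplace"          # "laplace" | "raw"
    chance_test: str = "wilcoxon"        # "wilcoxon" | "mannwhitney"
    # signal front end
    target_rate_hz: float = 100.0
    filter_cutoff_hz: float = 20.0
    filter_order: int = 4
    zero_phase: bool = True
    accel_weight: float = 0.02
    accel_units: str = "g"
    # phases to analyse
    phases: tuple[str, ...] = ("PotentialThreat", "Startle", "ResponseModulation")
    # XLSX reader mapping (layout differs between deposits)
    xlsx_sheet: str | int = 0
    xlsx_column_map: dict = field(default_factory=dict)
    xlsx_diagnosis_column: str = "diagnosis"
    xlsx_subject_column: str | None = None

    def validate(self) -> "RunConfig":
        if self.k_features < 1:
            raise ConfigError("k_features must be >= 1")
        if not 0.0 < self.threshold < 1.0:
            raise ConfigError("threshold must lie in (0, 1)")
        if self.db_scatter_exponent not in (1, 2):
            raise ConfigError("db_scatter_exponent must be 1 or 2")
        if self.permutations < 1:
            raise ConfigError("permutations must be >= 1")
        if self.beta_shape not in ("laplace", "raw"):
            raise ConfigError(f"unknown beta_shape {self.beta_shape!r}")
        if self.chance_test not in ("wilcoxon", "mannwhitney"):
            raise ConfigError(f"unknown chance_test {self.chance_test!r}")
        if not 0.0 < self.accel_weight < 1.0:
            raise ConfigError("accel_weight must lie in (0, 1)")
        if self.accel_units not in ("g", "m/s2"):
            raise ConfigError(f"unknown accel_units {self.accel_units!r}")
        if self.filter_cutoff_hz >= self.target_rate_hz / 2:
            raise ConfigError("filter cutoff must be below Nyquist")
        from .segmentation import PHASE_WINDOWS
        for ph in self.phases:
            if ph not in PHASE_WINDOWS:
                raise ConfigError(f"unknown phase {ph!r}")
        return self

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["phases"] = list(self.phases)
        return d


def load_config(path: str | Path | None) -> RunConfig:
    """Load a JSON or YAML config file; missing path means defaults."""
    if path is None:
        return RunConfig().validate()
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
    if "phases" in data:
        data["phases"] = tuple(data["phases"])
    return RunConfig(**data).validate()


def config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(cfg.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
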