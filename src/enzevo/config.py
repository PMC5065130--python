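"""Run configuration: thresholds and statistical-test options.

Defaults reproduce the analysis constants used throughout the package: a
1.3-fold neutrality band, a 2-fold boundary for strongly deleterious effects,
alpha = 0.05 and 95% confidence intervals.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class RunConfig:
    #: fold-change below 1/neutral_fold (above neutral_fold) is a candidate
    #: deleterious (favorable) call
    neutral_fold: float = 1.3
    #: DFE boundary between weakly and strongly deleterious
    strong_fold: float = 2.0
    alpha: float = 0.05
    ci_level: float = 0.95
    #: "student" (equal-variance) or "welch"
    t_test: str = "student"
    #: t-test on log10-transformed activities (multiplicative errors) or raw
    log_scale: bool = True
    #: per-batch fold aggregation: "geometric" or "arithmetic"
    batch_agg: str = "geometric"
    #: binomial CI method for DFE frequencies: "wilson" or "clopper-pearson"
    binomial_ci: str = "wilson"
    #: optional Benjamini-Hochberg correction of per-mutation p-values
    multiple_testing: str | None = None
    #: generalist-window retention threshold (fold below each activity's max)
    retention_fold: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.neutral_fold > 1:
            raise ConfigError("neutral_fold must be > 1")
        if not self.strong_fold > 1:
            raise ConfigError("strong_fold must be > 1")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if not 0 < self.ci_level < 1:
            raise ConfigError("ci_level must be in (0, 1)")
        if self.t_test not in ("student", "welch"):
            raise ConfigError("t_test must be 'student' or 'welch'")
        if self.batch_agg not in ("geometric", "arithmetic"):
            raise ConfigError("batch_agg must be 'geometric' or 'arithmetic'")
        if self.binomial_ci not in ("wilson", "clopper-pearson"):
            raise ConfigError("binomial_ci must be 'wilson' or 'clopper-pearson'")
        if self.multiple_testing not in (None, "bh"):
            raise ConfigError("multiple_testing must be None or 'bh'")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must hold key: value pairs")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        """Stable digest of the configuration, for run provenance logs."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


DEFAULT_CONFIG = RunConfig()
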