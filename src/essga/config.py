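"""Run configuration: schema, defaults and validation for experiment runs."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import yaml

from .scenarios import BUILTIN_SCENARIOS

__all__ = ["RunConfig", "validate_config", "ALL_METHODS"]

ALL_METHODS = ("regression", "summary_statistic", "posterior_mean", "analytic")

_KNOWN_KEYS = {
    "scenarios", "methods", "M", "K", "B", "seed", "output_path", "log_level",
}


@dataclass
class RunConfig:
    """Validated configuration for an experiment-grid run.

    Defaults mirror the simulation conditions of the built-in study:
    M = 1e5 prior draws per scenario, K = 1e4 datasets for the posterior-mean
    comparator, B = 1000 bootstrap replicates.
    """

    scenarios: List[str] = field(
        default_factory=lambda: list(BUILTIN_SCENARIOS)
    )
    methods: List[str] = field(default_factory=lambda: list(ALL_METHODS))
    M: int = 100_000
    K: int = 10_000
    B: int = 1000
    seed: int = 1
    output_path: Optional[str] = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.scenarios:
            raise ValueError("scenarios must be a nonempty list")
        if not self.methods:
            raise ValueError("methods must be a nonempty list")
        unknown = [m for m in self.methods if m not in ALL_METHODS]
        if unknown:
            raise ValueError(
                f"unknown methods {unknown}; choose from {list(ALL_METHODS)}"
            )
        bad = [s for s in self.scenarios if s not in BUILTIN_SCENARIOS]
        if bad:
            raise ValueError(
                f"unknown scenario name(s) {bad}; built-ins are "
                f"{sorted(BUILTIN_SCENARIOS)}"
            )
        if self.M < 2:
            raise ValueError(f"M must be >= 2, got {self.M}")
        if self.K < 2:
            raise ValueError(f"K must be >= 2, got {self.K}")
        if self.B < 0:
            raise ValueError(f"B must be >= 0 (0 disables bootstrap CIs)")
        if self.log_level.upper() not in (
            "DEBUG", "INFO", "WARNING", "ERROR",
        ):
            raise ValueError(f"unknown log_level {self.log_level!r}")


def validate_config(path) -> RunConfig:
    """Parse and range-check a YAML run configuration file.

    Unknown keys are rejected with the offending key named; a minimal (even
    empty) mapping yields the documented defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a key-value mapping")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(
            f"{path}: unknown config key(s) {sorted(unknown)}; "
            f"known keys are {sorted(_KNOWN_KEYS)}"
        )
    return RunConfig(**raw)
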