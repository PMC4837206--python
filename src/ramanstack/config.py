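"""Run configuration: YAML schema, validation, and default resolution.

A run configuration declares the sample-preparation dialect, the two
condition groups (each either a list of cube directories or a phantom
specification with a measurement count), the preprocessing and profiling
parameters, and the significance level.  All randomness flows from the
single top-level ``seed`` through per-stack derived seeds, so individual
stages are reproducible in isolation.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .calibration import derive_seeds
from .errors import ConfigError
from .phantom import PhantomConfig
from .preprocess import PreprocessConfig
from .profile import DEFAULT_N_UPPER, DEFAULT_SIGNAL_FRACTION_THRESHOLD

__all__ = ["ConditionInput", "RunConfig", "load_run_config"]

RUN_CONFIG_VERSION = 1
CONDITION_NAMES = ("control", "metastasis")


@dataclass
class ConditionInput:
    """Inputs of one condition: cube directories or a phantom spec."""

    name: str
    cubes: list[str] = field(default_factory=list)
    phantom: dict[str, Any] | None = None
    n_measurements: int = 0

    def __post_init__(self) -> None:
        if bool(self.cubes) == (self.phantom is not None):
            raise ConfigError(
                f"condition {self.name!r} must declare exactly one of 'cubes' or 'phantom'"
            )
        if self.phantom is not None and self.n_measurements < 2:
            raise ConfigError(
                f"condition {self.name!r}: phantom input needs n_measurements >= 2"
            )
        if self.cubes and len(self.cubes) < 2:
            raise ConfigError(f"condition {self.name!r} needs >= 2 measurements")


@dataclass
class RunConfig:
    """Fully resolved configuration of one end-to-end run."""

    dialect: str
    conditions: dict[str, ConditionInput]
    seed: int = 0
    alpha: float = 0.05
    test_variant: str = "welch"
    bonferroni: bool = False
    n_upper: int = DEFAULT_N_UPPER
    signal_fraction_threshold: float = DEFAULT_SIGNAL_FRACTION_THRESHOLD
    preprocess: dict[str, Any] = field(default_factory=dict)
    write_cubes: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.dialect not in ("fixed", "unfixed"):
            raise ConfigError(f"unknown dialect {self.dialect!r}; valid: fixed, unfixed")
        if set(self.conditions) != set(CONDITION_NAMES):
            raise ConfigError(
                f"conditions must be exactly {CONDITION_NAMES}, got {sorted(self.conditions)}"
            )
        if not 0 < self.alpha <= 1:
            raise ConfigError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.test_variant not in ("welch", "student"):
            raise ConfigError(f"unknown test_variant {self.test_variant!r}")
        # validate preprocess overrides eagerly
        self.preprocess_config()
        for cond in self.conditions.values():
            if cond.phantom is not None:
                self.phantom_config(cond.name)

    def preprocess_config(self) -> PreprocessConfig:
        block = dict(self.preprocess)
        if "normalization_region" in block and block["normalization_region"] is not None:
            block["normalization_region"] = tuple(block["normalization_region"])
        unknown = set(block) - set(PreprocessConfig.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown preprocess config keys: {sorted(unknown)}")
        block.setdefault("dialect", self.dialect)
        if block["dialect"] != self.dialect:
            raise ConfigError(
                "preprocess dialect must match the run dialect "
                f"({block['dialect']!r} != {self.dialect!r})"
            )
        return PreprocessConfig(**block)

    def phantom_config(self, condition: str, seed: int | None = None) -> PhantomConfig:
        cond = self.conditions[condition]
        if cond.phantom is None:
            raise ConfigError(f"condition {condition!r} has no phantom block")
        block = dict(cond.phantom)
        block.setdefault("dialect", self.dialect)
        if block["dialect"] != self.dialect:
            raise ConfigError(
                "phantom dialect must match the run dialect "
                f"({block['dialect']!r} != {self.dialect!r})"
            )
        if seed is not None:
            block["seed"] = int(seed)
        else:
            block.setdefault("seed", self.seed)
        return PhantomConfig.from_dict(block)

    def stack_seeds(self) -> dict[str, list[int]]:
        """Per-condition derived stack seeds from the top-level seed."""
        counts = {
            name: (cond.n_measurements if cond.phantom is not None else len(cond.cubes))
            for name, cond in self.conditions.items()
        }
        total = sum(counts.values())
        seeds = derive_seeds(self.seed, total)
        out: dict[str, list[int]] = {}
        offset = 0
        for name in CONDITION_NAMES:
            n = counts[name]
            out[name] = [int(s) for s in seeds[offset : offset + n]]
            offset += n
        return out

    def resolved_dict(self) -> dict[str, Any]:
        """All defaults materialized, for the run-directory snapshot."""
        pp = self.preprocess_config()
        out: dict[str, Any] = {
            "format_version": RUN_CONFIG_VERSION,
            "dialect": self.dialect,
            "seed": self.seed,
            "alpha": self.alpha,
            "test_variant": self.test_variant,
            "bonferroni": self.bonferroni,
            "n_upper": self.n_upper,
            "signal_fraction_threshold": self.signal_fraction_threshold,
            "write_cubes": self.write_cubes,
            "log_level": self.log_level,
            "preprocess": {
                "dialect": pp.dialect,
                "baseline_method": pp.baseline_method,
                "normalization_region": list(pp.normalization_region),
                "despike_threshold": pp.despike_threshold,
                "despike_window": pp.despike_window,
                "despike_rel_floor": pp.despike_rel_floor,
            },
            "conditions": {},
        }
        for name, cond in self.conditions.items():
            if cond.phantom is not None:
                out["conditions"][name] = {
                    "n_measurements": cond.n_measurements,
                    "phantom": self.phantom_config(name).to_dict(),
                }
            else:
                out["conditions"][name] = {"cubes": list(cond.cubes)}
        return out


def _build_run_config(raw: dict[str, Any]) -> RunConfig:
    raw = copy.deepcopy(raw)
    version = raw.pop("format_version", RUN_CONFIG_VERSION)
    if version != RUN_CONFIG_VERSION:
        raise ConfigError(f"unsupported run config format_version {version!r}")
    if "dialect" not in raw:
        raise ConfigError("run config is missing required key 'dialect'")
    if "conditions" not in raw or not isinstance(raw["conditions"], dict):
        raise ConfigError("run config is missing the 'conditions' mapping")
    conditions = {}
    for name, block in raw.pop("conditions").items():
        if not isinstance(block, dict):
            raise ConfigError(f"condition {name!r} must be a mapping")
        conditions[name] = ConditionInput(
            name=name,
            cubes=list(block.get("cubes", [])),
            phantom=block.get("phantom"),
            n_measurements=int(block.get("n_measurements", 0)),
        )
    known = set(RunConfig.__dataclass_fields__) - {"conditions"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown run config keys: {sorted(unknown)}")
    return RunConfig(conditions=conditions, **raw)


def load_run_config(path: str | Path, overrides: dict[str, Any] | None = None) -> RunConfig:
    """Load and validate a YAML run configuration.

    ``overrides`` (CLI flags) take precedence over file keys.
    """
    path = Path(path)
    if not path.is_file():
        raise ConfigError(f"run config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"run config {path} must be a YAML mapping")
    if overrides:
        raw.update({k: v for k, v in overrides.items() if v is not None})
    return _build_run_config(raw)
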