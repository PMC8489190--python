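"""Run configuration: YAML parsing and validation for the command line.

A run configuration fully describes one anonymization run — input table,
attribute roles and hierarchy files, privacy model, quality model,
transformation model, search algorithm, budget, and seed — so that every run
report can embed it and be re-executed verbatim.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .search import GAConfig, SearchBudget

__all__ = ["RunConfig", "ConfigError", "parse_config", "config_from_mapping"]


class ConfigError(ValueError):
    """Invalid run configuration; the message names the offending key."""


_TOP_KEYS = {
    "input", "delimiter", "hierarchy_delimiter", "quasi_identifiers",
    "identifying", "privacy", "quality", "transformation", "local_iterations",
    "algorithm", "genetic", "budget", "seed", "output", "report",
    "suppression_token", "exhaustive_cap",
}
_PRIVACY_KEYS = {"model", "k", "threshold", "sampling_fraction"}
_BUDGET_KEYS = {"time_limit", "max_evaluations"}
_GA_KEYS = {"elite_fraction", "crossover_fraction", "production_fraction",
            "mutation_probability", "immigration_fraction",
            "immigration_interval", "iterations", "subpopulation_size"}
_ALGORITHMS = {"exhaustive", "bottom_up", "top_down", "genetic"}


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of one anonymization run."""

    input: str
    quasi_identifiers: dict[str, str]  # attribute name -> hierarchy path
    privacy_model: str
    k: int | None = None
    threshold: float | None = None
    sampling_fraction: float | None = None
    identifying: tuple[str, ...] = ()
    delimiter: str = ","
    hierarchy_delimiter: str = ";"
    quality: str = "granularity"
    transformation: str = "global"
    local_iterations: int = 100
    algorithm: str = "top_down"
    genetic: GAConfig = field(default_factory=GAConfig)
    budget: SearchBudget = field(default_factory=SearchBudget)
    seed: int = 0
    output: str | None = None
    report: str | None = None
    suppression_token: str = "*"
    exhaustive_cap: int = 100_000

    def echo(self) -> dict[str, Any]:
        """Plain mapping that re-parses to an equivalent RunConfig."""
        privacy: dict[str, Any] = {"model": self.privacy_model}
        if self.privacy_model == "k_anonymity":
            privacy["k"] = self.k
        else:
            privacy["threshold"] = self.threshold
            privacy["sampling_fraction"] = self.sampling_fraction
        return {
            "input": self.input,
            "delimiter": self.delimiter,
            "hierarchy_delimiter": self.hierarchy_delimiter,
            "quasi_identifiers": dict(self.quasi_identifiers),
            "identifying": list(self.identifying),
            "privacy": privacy,
            "quality": self.quality,
            "transformation": self.transformation,
            "local_iterations": self.local_iterations,
            "algorithm": self.algorithm,
            "genetic": asdict(self.genetic),
            "budget": {"time_limit": self.budget.time_limit,
                       "max_evaluations": self.budget.max_evaluations},
            "seed": self.seed,
            "output": self.output,
            "report": self.report,
            "suppression_token": self.suppression_token,
            "exhaustive_cap": self.exhaustive_cap,
        }


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


def config_from_mapping(raw: Mapping[str, Any],
                        base_dir: Path | None = None) -> RunConfig:
    """Validate a plain mapping into a :class:`RunConfig`.

    Unknown keys, missing hierarchies, and invalid fractions raise
    :class:`ConfigError` messages naming the key.
    """
    unknown = set(raw) - _TOP_KEYS
    _require(not unknown, f"unknown configuration key(s): {sorted(unknown)}")
    _require("input" in raw, "missing required key 'input'")
    qi = raw.get("quasi_identifiers")
    _require(isinstance(qi, Mapping) and qi,
             "'quasi_identifiers' must map attribute names to hierarchy paths")
    for name, path in qi.items():
        _require(isinstance(path, str) and path,
                 f"quasi_identifiers.{name}: hierarchy path required")

    privacy = raw.get("privacy")
    _require(isinstance(privacy, Mapping), "'privacy' section required")
    unknown = set(privacy) - _PRIVACY_KEYS
    _require(not unknown, f"unknown privacy key(s): {sorted(unknown)}")
    model = privacy.get("model")
    _require(model in ("k_anonymity", "population_uniqueness"),
             "privacy.model must be 'k_anonymity' or 'population_uniqueness'")
    k = threshold = sampling_fraction = None
    if model == "k_anonymity":
        _require("k" in privacy, "privacy.k is required for k_anonymity "
                                 "(no silent default)")
        k = privacy["k"]
        _require(isinstance(k, int) and k >= 1, "privacy.k must be an integer >= 1")
    else:
        _require("threshold" in privacy,
                 "privacy.threshold is required for population_uniqueness")
        threshold = float(privacy["threshold"])
        _require(0.0 <= threshold <= 1.0, "privacy.threshold must be in [0, 1]")
        sampling_fraction = float(privacy.get("sampling_fraction", 1.0))
        _require(0.0 < sampling_fraction <= 1.0,
                 "privacy.sampling_fraction must be in (0, 1]")

    quality = raw.get("quality", "granularity")
    _require(quality == "granularity", "quality: only 'granularity' is supported")
    transformation = raw.get("transformation", "global")
    _require(transformation in ("global", "local"),
             "transformation must be 'global' or 'local'")
    algorithm = raw.get("algorithm", "top_down")
    _require(algorithm in _ALGORITHMS,
             f"algorithm must be one of {sorted(_ALGORITHMS)}")

    ga_raw = dict(raw.get("genetic") or {})
    unknown = set(ga_raw) - _GA_KEYS
    _require(not unknown, f"unknown genetic key(s): {sorted(unknown)}")
    try:
        genetic = GAConfig(**ga_raw)
    except ValueError as exc:
        raise ConfigError(f"genetic: {exc}") from None

    budget_raw = dict(raw.get("budget") or {})
    unknown = set(budget_raw) - _BUDGET_KEYS
    _require(not unknown, f"unknown budget key(s): {sorted(unknown)}")
    try:
        budget = SearchBudget(**budget_raw)
    except ValueError as exc:
        raise ConfigError(f"budget: {exc}") from None

    local_iterations = int(raw.get("local_iterations", 100))
    _require(local_iterations >= 1, "local_iterations must be >= 1")
    seed = int(raw.get("seed", 0))

    def resolve(p: str) -> str:
        path = Path(p)
        if base_dir is not None and not path.is_absolute():
            path = base_dir / path
        return str(path)

    cfg = RunConfig(
        input=resolve(str(raw["input"])),
        quasi_identifiers={str(n): resolve(str(p)) for n, p in qi.items()},
        privacy_model=model, k=k, threshold=threshold,
        sampling_fraction=sampling_fraction,
        identifying=tuple(raw.get("identifying") or ()),
        delimiter=str(raw.get("delimiter", ",")),
        hierarchy_delimiter=str(raw.get("hierarchy_delimiter", ";")),
        quality=quality, transformation=transformation,
        local_iterations=local_iterations, algorithm=algorithm,
        genetic=genetic, budget=budget, seed=seed,
        output=resolve(str(raw["output"])) if raw.get("output") else None,
        report=resolve(str(raw["report"])) if raw.get("report") else None,
        suppression_token=str(raw.get("suppression_token", "*")),
        exhaustive_cap=int(raw.get("exhaustive_cap", 100_000)),
    )
    _require(Path(cfg.input).exists(), f"input: file not found: {cfg.input}")
    for name, path in cfg.quasi_identifiers.items():
        _require(Path(path).exists(),
                 f"quasi_identifiers.{name}: hierarchy file not found: {path}")
    return cfg


def parse_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    with path.open(encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{path}: configuration must be a mapping")
    return config_from_mapping(raw, base_dir=path.parent)
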