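"""Synthetic categorical microdata, balanced hierarchies, and a benchmark harness.

The generator emulates the shape of the categorical survey/registry tables the
anonymization algorithms are designed for: per attribute a finite domain of
coded values drawn uniformly or with Zipf skew (skewed marginals produce the
mix of rare and common quasi-identifier combinations that makes suppression
behavior non-trivial), plus a balanced hierarchy that merges ``b`` adjacent
codes per level.  Everything is deterministic per seed, so fixtures are
generated at test time instead of being shipped.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import (AttributeDefinition, Dataset, GeneralizationHierarchy,
                         Role)
from .local import LocalRecodingConfig, anonymize_local
from .privacy import KAnonymity, PrivacyModel
from .search import AnonymizationContext, GAConfig, SearchBudget, run_search

__all__ = [
    "AttributeSpec",
    "SyntheticSpec",
    "balanced_hierarchy",
    "generate_dataset",
    "toy8",
    "BenchmarkRun",
    "run_benchmark",
]


@dataclass(frozen=True)
class AttributeSpec:
    """One synthetic attribute: domain size, hierarchy fan-out, marginal shape."""

    domain_size: int
    branching_factor: int = 2
    distribution: str = "uniform"  # "uniform" or "zipf"
    zipf_s: float = 1.0

    def __post_init__(self) -> None:
        if self.domain_size < 1:
            raise ValueError("domain_size must be >= 1")
        if self.branching_factor < 2:
            raise ValueError("branching_factor must be >= 2")
        if self.distribution not in ("uniform", "zipf"):
            raise ValueError(f"unknown distribution {self.distribution!r}")


@dataclass(frozen=True)
class SyntheticSpec:
    """Blueprint for one synthetic dataset."""

    n_records: int
    attributes: tuple[AttributeSpec, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records < 0:
            raise ValueError("n_records must be >= 0")


def balanced_hierarchy(name: str, domain_size: int,
                       branching_factor: int) -> GeneralizationHierarchy:
    """Balanced hierarchy over zero-padded codes ``0 .. domain_size - 1``.

    Level ``l`` groups leaves into blocks of ``branching_factor ** l``
    consecutive codes, labelled ``"[lo-hi]"``; the top level (block covering
    the whole domain) is ``"*"``.  Height is ``ceil(log_b(domain_size))``.
    """
    d, b = domain_size, branching_factor
    height = 0
    while b ** height < d:
        height += 1
    width = len(str(d - 1))
    rows = []
    for code in range(d):
        row = [str(code).zfill(width)]
        for level in range(1, height + 1):
            block = b ** level
            lo = (code // block) * block
            hi = min(lo + block - 1, d - 1)
            row.append("*" if level == height else f"[{lo}-{hi}]")
        rows.append(tuple(row))
    return GeneralizationHierarchy(name, tuple(rows))


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[Dataset, list[GeneralizationHierarchy]]:
    """Draw a synthetic dataset plus matching balanced hierarchies."""
    rng = np.random.default_rng(spec.seed)
    hierarchies = []
    columns = {}
    attrs = []
    for idx, aspec in enumerate(spec.attributes):
        name = f"attr{idx}"
        hier = balanced_hierarchy(name, aspec.domain_size, aspec.branching_factor)
        d = aspec.domain_size
        if aspec.distribution == "uniform":
            codes = rng.integers(0, d, size=spec.n_records)
        else:
            p = 1.0 / np.arange(1, d + 1, dtype=np.float64) ** aspec.zipf_s
            p /= p.sum()
            codes = rng.choice(d, size=spec.n_records, p=p)
        width = len(str(d - 1))
        columns[name] = [str(int(c)).zfill(width) for c in codes]
        hierarchies.append(hier)
        attrs.append(AttributeDefinition(name, Role.QUASI_IDENTIFYING, hier))
    frame = pd.DataFrame(columns, dtype=object) if columns else pd.DataFrame(
        index=range(spec.n_records))
    if spec.n_records == 0 and columns:
        frame = pd.DataFrame({k: pd.Series([], dtype=object) for k in columns})
    return Dataset(tuple(attrs), frame), hierarchies


def toy8() -> Dataset:
    """The eight-record (age, sex) worked example used throughout the docs.

    Ages generalize exact -> decade -> ``*``; sex generalizes to ``*``.  At
    level (0, 0) the records pair up into four classes of two; at (2, 0) they
    collapse into two classes of four (one per sex).
    """
    age_rows = (("34", "30-39", "*"), ("45", "40-49", "*"),
                ("66", "60-69", "*"), ("70", "70-79", "*"))
    sex_rows = (("M", "*"), ("F", "*"))
    age_h = GeneralizationHierarchy("age", age_rows)
    sex_h = GeneralizationHierarchy("sex", sex_rows)
    records = [("34", "M"), ("34", "M"), ("45", "F"), ("45", "F"),
               ("66", "M"), ("70", "F"), ("66", "M"), ("70", "F")]
    frame = pd.DataFrame(records, columns=["age", "sex"], dtype=object)
    attrs = (AttributeDefinition("age", Role.QUASI_IDENTIFYING, age_h),
             AttributeDefinition("sex", Role.QUASI_IDENTIFYING, sex_h))
    return Dataset(attrs, frame)


# ---------------------------------------------------------------------------
# benchmark harness
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BenchmarkRun:
    """One benchmark cell: dataset x algorithm x privacy x transformation."""

    dataset_id: str
    spec: SyntheticSpec
    algorithm: str
    model: PrivacyModel = field(default_factory=lambda: KAnonymity(5))
    transformation: str = "global"  # or "local"
    budget: SearchBudget | None = None
    local_iterations: int = 100
    ga_config: GAConfig | None = None
    seed: int = 0


def run_benchmark(plan: Sequence[BenchmarkRun],
                  repetitions: int = 5) -> pd.DataFrame:
    """Execute every run ``repetitions`` times (seeds ``seed + rep``).

    Returns a long-format table with one row per repetition: dataset,
    algorithm, privacy model, transformation, repetition, elapsed seconds,
    evaluations, and final quality.  Timings are recorded, never asserted:
    they are hardware-dependent.  Failures of individual runs are recorded
    (``error`` column) and the remaining runs proceed.
    """
    if not plan:
        raise ValueError("benchmark plan is empty")
    rows = []
    for run in plan:
        for rep in range(repetitions):
            seed = run.seed + rep
            record = {
                "dataset": run.dataset_id, "algorithm": run.algorithm,
                "model": type(run.model).__name__,
                "transformation": run.transformation, "rep": rep, "seed": seed,
                "elapsed": np.nan, "evaluations": np.nan, "quality": np.nan,
                "error": "",
            }
            try:
                ds, _ = generate_dataset(run.spec)
                t0 = time.perf_counter()
                if run.transformation == "local":
                    cfg = LocalRecodingConfig(
                        iterations=run.local_iterations,
                        inner_algorithm=run.algorithm,
                        per_iteration_budget=run.budget)
                    res = anonymize_local(ds, run.model, cfg,
                                          ga_config=run.ga_config, seed=seed)
                else:
                    ctx = AnonymizationContext(ds, run.model)
                    res = run_search(ctx, run.algorithm, budget=run.budget,
                                     ga_config=run.ga_config, seed=seed)
                record["elapsed"] = time.perf_counter() - t0
                record["evaluations"] = res.evaluations
                record["quality"] = res.quality
            except Exception as exc:  # noqa: BLE001 - keep the harness running
                record["error"] = f"{type(exc).__name__}: {exc}"
            rows.append(record)
    return pd.DataFrame(rows)
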