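"""Global recoding, equivalence classes, record suppression, and quality scoring.

Applying a generalization scheme recodes every quasi-identifier (QI) cell to
its hierarchy value at the scheme's level for that attribute.  Records that
would violate the privacy model are *suppressed*: their QI cells are replaced
by the suppression token and they are excluded from privacy evaluation (the
rows themselves are retained in the output).

Output quality is measured with the granularity model: each QI cell incurs a
loss between 0 (untouched leaf) and 1 (suppressed, or generalized to a value
covering the whole domain), and the score is ``100 * (1 - mean cell loss)``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import Dataset, Scheme

if TYPE_CHECKING:  # pragma: no cover
    from .privacy import PrivacyModel

__all__ = [
    "SUPPRESSION_TOKEN",
    "EquivalenceClassHistogram",
    "TransformedDataset",
    "apply_scheme",
    "equivalence_classes",
    "suppress_to_satisfy",
    "quality_granularity",
]

SUPPRESSION_TOKEN = "*"


@dataclass(frozen=True)
class EquivalenceClassHistogram:
    """Multiset of equivalence-class sizes among non-suppressed records."""

    sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.sizes):
            raise ValueError("class sizes must be positive")

    @property
    def n_effective(self) -> int:
        """Number of non-suppressed records."""
        return int(sum(self.sizes))

    @property
    def n_classes(self) -> int:
        return len(self.sizes)

    @property
    def n_singletons(self) -> int:
        return sum(1 for s in self.sizes if s == 1)

    def as_counter(self) -> Counter:
        return Counter(self.sizes)


@dataclass
class TransformedDataset:
    """Result of recoding a dataset: generalized cells plus a suppression set.

    ``schemes`` maps each record's positional index to the generalization
    scheme applied to it (identical for all records under global recoding,
    per-partition under local recoding).  Suppressed records keep an entry but
    their QI cells hold the suppression token.
    """

    original: Dataset
    frame: pd.DataFrame
    schemes: tuple[Scheme, ...]
    suppressed: frozenset[int] = frozenset()
    suppression_token: str = SUPPRESSION_TOKEN

    @property
    def n_records(self) -> int:
        return len(self.frame)

    @property
    def n_suppressed(self) -> int:
        return len(self.suppressed)

    def scheme_for(self, record: int) -> Scheme:
        return self.schemes[record]


def apply_scheme(ds: Dataset, scheme: Scheme,
                 suppression_token: str = SUPPRESSION_TOKEN) -> TransformedDataset:
    """Globally recode every QI cell to its hierarchy value at the scheme level.

    Non-QI cells are untouched; the suppression set starts empty.  A QI value
    absent from its hierarchy raises ``KeyError`` naming attribute and value.
    """
    qi = ds.quasi_identifiers
    if len(scheme) != len(qi):
        raise ValueError(f"scheme length {len(scheme)} != {len(qi)} quasi-identifiers")
    frame = ds.frame.copy()
    for g, attr in zip(scheme, qi):
        hier = attr.hierarchy
        if hier is None:
            raise ValueError(f"quasi-identifier {attr.name!r} has no hierarchy")
        mapping = hier.mapping(g)
        col = frame[attr.name]
        mapped = col.map(mapping)
        if mapped.isna().any():
            bad = col[mapped.isna()].iloc[0]
            raise KeyError(
                f"value {bad!r} of attribute {attr.name!r} is not a hierarchy leaf")
        frame[attr.name] = mapped
    return TransformedDataset(
        original=ds, frame=frame, schemes=(scheme,) * ds.n_records,
        suppressed=frozenset(), suppression_token=suppression_token)


def equivalence_classes(
    t: TransformedDataset,
) -> tuple[EquivalenceClassHistogram, list[list[int]]]:
    """Partition non-suppressed records by their full QI tuple.

    Returns the class-size histogram and the record-index groups in order of
    first occurrence.  Suppressed records are excluded.
    """
    qi_names = list(t.original.qi_names)
    groups: dict[tuple, list[int]] = {}
    if qi_names:
        cols = [t.frame[name].to_numpy() for name in qi_names]
        for idx in range(len(t.frame)):
            if idx in t.suppressed:
                continue
            key = tuple(c[idx] for c in cols)
            groups.setdefault(key, []).append(idx)
    else:
        members = [i for i in range(len(t.frame)) if i not in t.suppressed]
        if members:
            groups[()] = members
    ordered = list(groups.values())
    hist = EquivalenceClassHistogram(tuple(len(g) for g in ordered))
    return hist, ordered


def _suppress(t: TransformedDataset, indices: Sequence[int]) -> TransformedDataset:
    if not indices:
        return t
    frame = t.frame.copy()
    qi_names = list(t.original.qi_names)
    frame.iloc[list(indices), [frame.columns.get_loc(n) for n in qi_names]] = \
        t.suppression_token
    return replace(t, frame=frame, suppressed=t.suppressed | frozenset(indices))


def suppress_to_satisfy(t: TransformedDataset, model: "PrivacyModel") -> TransformedDataset:
    """Suppress records until the transformed dataset satisfies ``model``.

    For k-anonymity exactly the records in classes of size < k are suppressed.
    For population uniqueness whole classes are suppressed in ascending order
    of class size (ties broken by first occurrence) until the estimated
    population uniqueness meets the threshold.  Suppressing everything always
    satisfies both models, so this never fails.
    """
    from .privacy import KAnonymity, PopulationUniqueness, estimate_population_uniqueness

    hist, groups = equivalence_classes(t)
    if isinstance(model, KAnonymity):
        doomed = [i for grp in groups if len(grp) < model.k for i in grp]
        return _suppress(t, doomed)
    if isinstance(model, PopulationUniqueness):
        sizes = list(hist.sizes)
        if not sizes:
            return t
        order = sorted(range(len(groups)), key=lambda j: (len(groups[j]), j))
        removed: list[int] = []
        current = Counter(sizes)
        while True:
            remaining = EquivalenceClassHistogram(
                tuple(s for s in current.elements()))
            if remaining.n_effective == 0:
                break
            est = estimate_population_uniqueness(remaining, model.sampling_fraction)
            if est <= model.threshold:
                break
            j = order[len(removed)]
            removed.append(j)
            current[len(groups[j])] -= 1
        doomed = [i for j in removed for i in groups[j]]
        return _suppress(t, doomed)
    raise TypeError(f"unsupported privacy model {model!r}")


def quality_granularity(original: Dataset, t: TransformedDataset) -> float:
    """Granularity quality score in percent.

    Per QI cell, loss ``(leaves(v) - 1) / (D - 1)`` where ``leaves(v)`` is the
    number of distinct leaf values covered by the cell's generalized value and
    ``D`` the attribute's total leaf count (loss 0 when ``D == 1``); suppressed
    cells lose 1.  Score = ``100 * (1 - mean loss over all QI cells)``.
    Datasets with zero records or zero quasi-identifiers score 100.
    """
    qi = original.quasi_identifiers
    n = original.n_records
    if n == 0 or not qi:
        return 100.0
    total_loss = 0.0
    suppressed = t.suppressed
    raw_cols = {a.name: original.frame[a.name].to_numpy() for a in qi}
    for idx in range(n):
        if idx in suppressed:
            total_loss += len(qi)
            continue
        scheme = t.schemes[idx]
        for g, attr in zip(scheme, qi):
            hier = attr.hierarchy
            assert hier is not None
            D = hier.n_leaves
            if D <= 1:
                continue
            v = hier.mapping(g)[raw_cols[attr.name][idx]]
            total_loss += (hier.leaf_count(v, g) - 1) / (D - 1)
    return 100.0 * (1.0 - total_loss / (n * len(qi)))
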