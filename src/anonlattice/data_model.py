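"""Core domain types: datasets, generalization hierarchies, and the scheme lattice.

A *generalization hierarchy* describes, for one quasi-identifying attribute,
how its raw values (level 0, the "leaves") are progressively coarsened into
broader categories (level 1, 2, ..., up to the hierarchy height ``L``).  A
*generalization scheme* assigns one level to each quasi-identifier; the set of
all schemes, ordered componentwise, forms the solution-space lattice searched
by the anonymization algorithms.

Cells are compared as exact strings: no trimming, no case folding, no type
coercion.  The empty string is an ordinary value and, for a quasi-identifier,
must appear as a hierarchy leaf like any other value.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from enum import Enum
from functools import cached_property
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Role",
    "AttributeDefinition",
    "Dataset",
    "GeneralizationHierarchy",
    "Lattice",
    "Scheme",
    "read_dataset",
    "write_dataset",
    "read_hierarchy",
    "write_hierarchy",
    "validate_hierarchy",
    "lattice_size",
    "neighbors",
]

#: A generalization scheme: one level per quasi-identifying attribute.
Scheme = tuple[int, ...]


class Role(str, Enum):
    """Disclosure role of an attribute."""

    IDENTIFYING = "identifying"
    QUASI_IDENTIFYING = "quasi_identifying"
    INSENSITIVE = "insensitive"


@dataclass(frozen=True)
class GeneralizationHierarchy:
    """Per-attribute coarsening table.

    ``table`` has one row per leaf value and ``L + 1`` columns; column ``l``
    holds the value the leaf is recoded to at generalization level ``l``
    (column 0 is the leaf itself).

    Parameters
    ----------
    attribute:
        Name of the attribute the hierarchy applies to.
    table:
        Tuple of rows, each a tuple of ``L + 1`` strings.
    """

    attribute: str
    table: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        if not self.table:
            raise ValueError(f"hierarchy for {self.attribute!r} has no rows")
        widths = {len(r) for r in self.table}
        if len(widths) != 1:
            raise ValueError(f"hierarchy for {self.attribute!r} has ragged rows")
        if next(iter(widths)) == 0:
            raise ValueError(f"hierarchy for {self.attribute!r} has zero columns")

    @property
    def height(self) -> int:
        """Maximum generalization level ``L`` (number of columns minus one)."""
        return len(self.table[0]) - 1

    @cached_property
    def leaves(self) -> frozenset[str]:
        return frozenset(row[0] for row in self.table)

    @property
    def n_leaves(self) -> int:
        return len(self.table)

    @cached_property
    def _maps(self) -> tuple[dict[str, str], ...]:
        return tuple({row[0]: row[level] for row in self.table}
                     for level in range(self.height + 1))

    def mapping(self, level: int) -> Mapping[str, str]:
        """Leaf -> generalized value at ``level``."""
        if not 0 <= level <= self.height:
            raise ValueError(
                f"level {level} outside [0, {self.height}] for {self.attribute!r}")
        return self._maps[level]

    @cached_property
    def _leaf_counts(self) -> tuple[dict[str, int], ...]:
        out = []
        for level in range(self.height + 1):
            counts: dict[str, int] = {}
            for row in self.table:
                counts[row[level]] = counts.get(row[level], 0) + 1
            out.append(counts)
        return tuple(out)

    def leaf_count(self, value: str, level: int) -> int:
        """Number of distinct leaves recoded to ``value`` at ``level``."""
        return self._leaf_counts[level].get(value, 0)


@dataclass(frozen=True)
class AttributeDefinition:
    """Name, role, and (for quasi-identifiers) hierarchy of one attribute.

    A quasi-identifying attribute may be declared before its hierarchy is
    attached (e.g. straight after parsing); any operation that needs to
    generalize it will demand the hierarchy.
    """

    name: str
    role: Role = Role.INSENSITIVE
    hierarchy: GeneralizationHierarchy | None = None


@dataclass
class Dataset:
    """A rectangular table of string cells with attribute-role annotations.

    ``frame`` is a pandas DataFrame of ``object`` dtype whose columns match
    ``attributes`` in order.
    """

    attributes: tuple[AttributeDefinition, ...]
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        names = [a.name for a in self.attributes]
        if len(set(names)) != len(names):
            raise ValueError("attribute names must be unique")
        if list(self.frame.columns) != names:
            raise ValueError("frame columns must match attribute names in order")

    @property
    def n_records(self) -> int:
        return len(self.frame)

    @property
    def quasi_identifiers(self) -> tuple[AttributeDefinition, ...]:
        return tuple(a for a in self.attributes if a.role is Role.QUASI_IDENTIFYING)

    @property
    def qi_names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.quasi_identifiers)

    @property
    def heights(self) -> tuple[int, ...]:
        out = []
        for a in self.quasi_identifiers:
            if a.hierarchy is None:
                raise ValueError(
                    f"quasi-identifying attribute {a.name!r} has no hierarchy")
            out.append(a.hierarchy.height)
        return tuple(out)

    def hierarchy(self, name: str) -> GeneralizationHierarchy:
        for a in self.attributes:
            if a.name == name:
                if a.hierarchy is None:
                    raise KeyError(f"attribute {name!r} has no hierarchy")
                return a.hierarchy
        raise KeyError(name)

    def with_hierarchies(
        self, hierarchies: Mapping[str, GeneralizationHierarchy]
    ) -> "Dataset":
        """Return a copy whose named attributes become quasi-identifying."""
        attrs = []
        unknown = set(hierarchies) - {a.name for a in self.attributes}
        if unknown:
            raise KeyError(f"hierarchies for unknown attributes: {sorted(unknown)}")
        for a in self.attributes:
            if a.name in hierarchies:
                attrs.append(AttributeDefinition(
                    a.name, Role.QUASI_IDENTIFYING, hierarchies[a.name]))
            else:
                attrs.append(a)
        return Dataset(tuple(attrs), self.frame)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

class ParseError(ValueError):
    """Malformed input table."""


def read_dataset(
    path: str | Path,
    delimiter: str = ",",
    roles: Mapping[str, Role | str] | None = None,
    hierarchies: Mapping[str, GeneralizationHierarchy] | None = None,
) -> Dataset:
    """Read a delimited text table (header row required) into a :class:`Dataset`.

    Cells are read verbatim as text.  Attributes not listed in ``roles``
    default to insensitive.  An attribute named in ``hierarchies`` becomes
    quasi-identifying regardless of ``roles``.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file, header row required") from None
        if len(set(header)) != len(header):
            dupes = sorted({c for c in header if header.count(c) > 1})
            raise ParseError(f"{path}: duplicate header names {dupes}")
        rows: list[list[str]] = []
        for i, row in enumerate(reader, start=1):
            if len(row) != len(header):
                raise ParseError(
                    f"{path}: row {i} has {len(row)} cells, expected {len(header)}")
            rows.append(row)

    roles = dict(roles or {})
    hierarchies = dict(hierarchies or {})
    unknown = (set(roles) | set(hierarchies)) - set(header)
    if unknown:
        raise ParseError(f"{path}: role/hierarchy given for unknown attribute(s) "
                         f"{sorted(unknown)}")
    attrs = []
    for name in header:
        role = Role(roles.get(name, Role.INSENSITIVE))
        hier = hierarchies.get(name)
        if hier is not None:
            role = Role.QUASI_IDENTIFYING
        attrs.append(AttributeDefinition(name, role, hier))
    frame = pd.DataFrame(rows, columns=header, dtype=object)
    return Dataset(tuple(attrs), frame)


def write_dataset(ds: Dataset | pd.DataFrame, path: str | Path,
                  delimiter: str = ",") -> None:
    """Write microdata as RFC-4180-style delimited text (round-trips bit-exactly)."""
    frame = ds.frame if isinstance(ds, Dataset) else ds
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(frame.columns)
        for row in frame.itertuples(index=False):
            writer.writerow(row)


def read_hierarchy(path: str | Path, delimiter: str = ";",
                   attribute: str | None = None) -> GeneralizationHierarchy:
    """Read a hierarchy file: one row per leaf-to-root path, no header.

    The file must satisfy the structural invariants (unique leaves, functional
    level-to-level mapping); violations raise :class:`ParseError`.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        rows = [tuple(r) for r in csv.reader(fh, delimiter=delimiter)]
    if not rows:
        raise ParseError(f"{path}: hierarchy file is empty")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ParseError(f"{path}: ragged hierarchy rows (widths {sorted(widths)})")
    if next(iter(widths)) == 0:
        raise ParseError(f"{path}: hierarchy rows have zero columns")
    hier = GeneralizationHierarchy(attribute or path.stem, tuple(rows))
    violations = validate_hierarchy(hier)
    if violations:
        raise ParseError(f"{path}: invalid hierarchy: " + "; ".join(violations))
    return hier


def write_hierarchy(h: GeneralizationHierarchy, path: str | Path,
                    delimiter: str = ";") -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        for row in h.table:
            writer.writerow(row)


def validate_hierarchy(
    h: GeneralizationHierarchy, observed: Iterable[str] = ()
) -> list[str]:
    """Check structural invariants; return a list of violations (empty = valid).

    Checks: leaves pairwise distinct; each level-to-level mapping functional;
    distinct-value counts non-increasing with level; every observed value is a
    leaf.  Violations are reported, never raised.
    """
    violations: list[str] = []
    seen: set[str] = set()
    for row in h.table:
        if row[0] in seen:
            violations.append(f"duplicate leaf {row[0]!r}")
        seen.add(row[0])
    for level in range(h.height):
        mapping: dict[str, str] = {}
        for row in h.table:
            prev = mapping.setdefault(row[level], row[level + 1])
            if prev != row[level + 1]:
                violations.append(
                    f"non-functional mapping at level {level}: {row[level]!r} -> "
                    f"both {prev!r} and {row[level + 1]!r}")
    counts = [len({row[level] for row in h.table}) for level in range(h.height + 1)]
    for level in range(h.height):
        if counts[level + 1] > counts[level]:
            violations.append(
                f"distinct-value count increases from level {level} "
                f"({counts[level]}) to level {level + 1} ({counts[level + 1]})")
    missing = sorted(set(observed) - h.leaves)
    for value in missing:
        violations.append(f"observed value {value!r} is not a hierarchy leaf")
    return violations


# ---------------------------------------------------------------------------
# lattice arithmetic
# ---------------------------------------------------------------------------

def lattice_size(heights: Sequence[int]) -> int:
    """Number of generalization schemes: the exact product of ``L_i + 1``.

    Python integers are arbitrary precision, so sizes far beyond 2**63
    (solution spaces of 30-attribute datasets) are exact.
    """
    for h in heights:
        if h < 0:
            raise ValueError(f"negative hierarchy height {h}")
    return math.prod(h + 1 for h in heights)


@dataclass(frozen=True)
class Lattice:
    """The solution space of all generalization schemes for given heights."""

    heights: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(h < 0 for h in self.heights):
            raise ValueError("heights must be non-negative")

    @property
    def size(self) -> int:
        return lattice_size(self.heights)

    @property
    def bottom(self) -> Scheme:
        return (0,) * len(self.heights)

    @property
    def top(self) -> Scheme:
        return self.heights

    def __contains__(self, g: Sequence[int]) -> bool:
        return (len(g) == len(self.heights)
                and all(0 <= gi <= hi for gi, hi in zip(g, self.heights)))

    def schemes(self):
        """Iterate all schemes in lexicographic order (use only for small lattices)."""
        import itertools
        return itertools.product(*(range(h + 1) for h in self.heights))


def neighbors(g: Scheme, lattice: Lattice, direction: str) -> list[Scheme]:
    """Single-step lattice neighbors of ``g``, in coordinate order.

    ``direction="up"`` increments one coordinate (bounded by the heights);
    ``"down"`` decrements one (bounded by zero).
    """
    if g not in lattice:
        raise ValueError(f"scheme {g} outside lattice bounds {lattice.heights}")
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    step = 1 if direction == "up" else -1
    out: list[Scheme] = []
    for i, (gi, hi) in enumerate(zip(g, lattice.heights)):
        ni = gi + step
        if 0 <= ni <= hi:
            out.append(g[:i] + (ni,) + g[i + 1:])
    return out
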