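"""Tridimensional DNA pooling designs and their inversion.

A mutagenized screening population is arrayed across 96-well plates and
every individual contributes DNA to exactly three pools:

* dimension **A** — one pool per *plate* (all wells of that plate),
* dimension **B** — one pool per *column*, taken across all plates,
* dimension **C** — one pool per *row*, taken across all plates.

For the canonical 8-plate, 8-row x 12-column layout this yields
8 + 12 + 8 = 28 pools over 768 individuals: A-pools of 96 members,
B-pools of 64 and C-pools of 96.  A rare variant whose frequency is
elevated in one pool of each dimension is traced back to the single
individual at the intersection of those pools; with pools from only two
dimensions the intersection narrows the source to a small subset that
can be re-tested individually.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional

import pandas as pd

__all__ = [
    "Dimension",
    "PoolId",
    "WellAddress",
    "Resolution",
    "DeconvolutionResult",
    "PoolingScheme",
    "build_scheme",
    "pools_of_individual",
    "deconvolve",
    "write_scheme",
    "read_scheme",
]


class Dimension(str, enum.Enum):
    """The three pooling dimensions, labelled A (plate), B (column), C (row)."""

    PLATE = "A"
    COLUMN = "B"
    ROW = "C"

    @classmethod
    def from_letter(cls, letter: str) -> "Dimension":
        for d in cls:
            if d.value == letter:
                return d
        raise ValueError(f"unknown pool dimension {letter!r} (expected A, B or C)")


class WellAddress(NamedTuple):
    """An individual's location: 1-based plate, row and column indices."""

    plate: int
    row: int
    column: int

    @property
    def label(self) -> str:
        return f"P{self.plate}R{self.row}C{self.column}"


class PoolId(NamedTuple):
    """One pool: a dimension (A/B/C) and a 1-based index within it."""

    dimension: Dimension
    index: int

    @property
    def label(self) -> str:
        return f"{self.dimension.value}{self.index}"

    @classmethod
    def parse(cls, label: str) -> "PoolId":
        label = label.strip()
        if len(label) < 2:
            raise ValueError(f"cannot parse pool label {label!r}")
        return cls(Dimension.from_letter(label[0]), int(label[1:]))


class Resolution(str, enum.Enum):
    """Outcome of deconvolving a set of flagged pools."""

    INDIVIDUAL = "INDIVIDUAL"  # exactly one well at a three-dimensional intersection
    SUBSET = "SUBSET"  # a small candidate set (two dimensions, or an ambiguous triple)
    NONE = "NONE"  # fewer than two dimensions represented, or empty intersection


@dataclass(frozen=True)
class DeconvolutionResult:
    candidates: frozenset
    resolution: Resolution

    @property
    def ambiguous(self) -> bool:
        """True when more than one individual is compatible with the flags."""
        return len(self.candidates) > 1


@dataclass(frozen=True)
class PoolingScheme:
    """A tridimensional pooling design over ``n_plates`` x ``n_rows`` x ``n_cols``.

    ``occupied`` optionally restricts the population to a subset of wells
    (a screen need not fill every plate); pools are computed over occupied
    wells only.  ``None`` means the full grid is occupied.
    """

    n_plates: int
    n_rows: int
    n_cols: int
    occupied: Optional[frozenset] = None

    def __post_init__(self) -> None:
        for name in ("n_plates", "n_rows", "n_cols"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.occupied is not None:
            object.__setattr__(self, "occupied", frozenset(self.occupied))
            for w in self.occupied:
                self._check_well(w)

    # -- population ---------------------------------------------------------

    def _check_well(self, well: WellAddress) -> None:
        if not (
            1 <= well.plate <= self.n_plates
            and 1 <= well.row <= self.n_rows
            and 1 <= well.column <= self.n_cols
        ):
            raise ValueError(f"well {well} outside scheme "
                             f"({self.n_plates}x{self.n_rows}x{self.n_cols})")

    def wells(self) -> list:
        """All occupied wells, in (plate, row, column) order."""
        if self.occupied is not None:
            return sorted(self.occupied)
        return [
            WellAddress(p, r, c)
            for p, r, c in itertools.product(
                range(1, self.n_plates + 1),
                range(1, self.n_rows + 1),
                range(1, self.n_cols + 1),
            )
        ]

    @property
    def population_size(self) -> int:
        if self.occupied is not None:
            return len(self.occupied)
        return self.n_plates * self.n_rows * self.n_cols

    # -- pools --------------------------------------------------------------

    def pools(self) -> list:
        """All pool ids: A1..A{plates}, B1..B{cols}, C1..C{rows}."""
        return (
            [PoolId(Dimension.PLATE, i) for i in range(1, self.n_plates + 1)]
            + [PoolId(Dimension.COLUMN, i) for i in range(1, self.n_cols + 1)]
            + [PoolId(Dimension.ROW, i) for i in range(1, self.n_rows + 1)]
        )

    def _check_pool(self, pool: PoolId) -> None:
        limits = {
            Dimension.PLATE: self.n_plates,
            Dimension.COLUMN: self.n_cols,
            Dimension.ROW: self.n_rows,
        }
        if not 1 <= pool.index <= limits[pool.dimension]:
            raise ValueError(f"pool {pool.label} outside scheme "
                             f"({self.n_plates}x{self.n_rows}x{self.n_cols})")

    def pools_of(self, well: WellAddress) -> tuple:
        """The (A, B, C) pool triple containing ``well``."""
        self._check_well(well)
        if self.occupied is not None and well not in self.occupied:
            raise ValueError(f"well {well} is not occupied in this scheme")
        return (
            PoolId(Dimension.PLATE, well.plate),
            PoolId(Dimension.COLUMN, well.column),
            PoolId(Dimension.ROW, well.row),
        )

    def members(self, pool: PoolId) -> frozenset:
        """The set of occupied wells contributing DNA to ``pool``."""
        self._check_pool(pool)
        dim = pool.dimension
        if dim is Dimension.PLATE:
            pred = lambda w: w.plate == pool.index
        elif dim is Dimension.COLUMN:
            pred = lambda w: w.column == pool.index
        else:
            pred = lambda w: w.row == pool.index
        return frozenset(w for w in self.wells() if pred(w))

    def pool_sizes(self) -> dict:
        return {p.label: len(self.members(p)) for p in self.pools()}


def build_scheme(
    n_plates: int, n_rows: int, n_cols: int, occupied: Optional[Iterable] = None
) -> PoolingScheme:
    """Construct the tridimensional pooling design.

    Deterministic for given dimensions.  Raises ``ValueError`` for
    non-positive dimensions or out-of-range occupied wells.
    """
    occ = frozenset(occupied) if occupied is not None else None
    return PoolingScheme(n_plates, n_rows, n_cols, occ)


def pools_of_individual(scheme: PoolingScheme, well: WellAddress) -> tuple:
    """The three pools (one per dimension) an individual belongs to."""
    return scheme.pools_of(well)


def deconvolve(scheme: PoolingScheme, flagged: Iterable[PoolId]) -> DeconvolutionResult:
    """Invert a set of flagged pools to candidate source individuals.

    Pools flagged within the same dimension are unioned first (two
    independent mutants in one run can light up two pools of a dimension),
    then member sets are intersected across the represented dimensions:

    * three dimensions, one well -> ``INDIVIDUAL``
    * three dimensions, several wells, or two dimensions -> ``SUBSET``
    * fewer than two dimensions, or empty intersection -> ``NONE``
    """
    flagged = list(flagged)
    for p in flagged:
        scheme._check_pool(p)
    by_dim: dict = {}
    for p in flagged:
        by_dim.setdefault(p.dimension, set()).update(scheme.members(p))
    if len(by_dim) <= 1:
        return DeconvolutionResult(frozenset(), Resolution.NONE)
    candidates = frozenset(
        set.intersection(*by_dim.values())
    )
    if not candidates:
        return DeconvolutionResult(frozenset(), Resolution.NONE)
    if len(by_dim) == 3 and len(candidates) == 1:
        return DeconvolutionResult(candidates, Resolution.INDIVIDUAL)
    return DeconvolutionResult(candidates, Resolution.SUBSET)


# -- serialization ----------------------------------------------------------

SCHEME_COLUMNS = ["sample_id", "plate", "row", "column", "pool_A", "pool_B", "pool_C"]


def scheme_to_frame(scheme: PoolingScheme) -> pd.DataFrame:
    rows = []
    for i, w in enumerate(scheme.wells(), start=1):
        a, b, c = scheme.pools_of(w)
        rows.append((f"S{i:04d}", w.plate, w.row, w.column, a.label, b.label, c.label))
    return pd.DataFrame(rows, columns=SCHEME_COLUMNS)


def write_scheme(scheme: PoolingScheme, path) -> None:
    scheme_to_frame(scheme).to_csv(path, sep="\t", index=False)


def read_scheme(path) -> PoolingScheme:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(SCHEME_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"scheme table missing columns: {sorted(missing)}")
    wells = frozenset(
        WellAddress(int(p), int(r), int(c))
        for p, r, c in zip(df["plate"], df["row"], df["column"])
    )
    n_plates = int(df["plate"].max())
    n_rows = int(df["row"].max())
    n_cols = int(df["column"].max())
    full = n_plates * n_rows * n_cols == len(wells)
    return PoolingScheme(n_plates, n_rows, n_cols, None if full else wells)
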