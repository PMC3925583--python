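"""Domain types and the bit-table algebra.

A binary *bit-table* has transactions as rows and items as columns; entry
(t, i) is 1 iff item i occurs in transaction t.  All support arithmetic in
this package reduces to integer linear algebra on such tables:

* the support of a single column ``b`` is the inner product ``bᵀb``
  (the count of its ones);
* the joint support of two columns is their inner product, so the full
  pairwise-support matrix of a table ``B`` is ``S = Bᵀ B``;
* the occurrence column of the union of two itemsets is the Hadamard
  (element-wise) product of their columns, i.e. the logical AND.

Entries are stored as small integers, so every support is an exact count
and no floating-point tolerance is needed anywhere downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "BitcloseError",
    "InvalidInputError",
    "ConfigError",
    "ContractViolationError",
    "MemoryGuardError",
    "TransactionDB",
    "BitTable",
    "SupportMatrix",
    "IndexTable",
    "Itemset",
    "Bicluster",
    "MiningConfig",
    "column_support",
    "pairwise_supports",
    "hadamard_column",
]


class BitcloseError(Exception):
    """Base class for all package errors."""


class InvalidInputError(BitcloseError, ValueError):
    """Raised when data violate a precondition (non-binary entries, shape mismatch)."""


class ConfigError(BitcloseError, ValueError):
    """Raised for out-of-range configuration values."""


class ContractViolationError(BitcloseError, RuntimeError):
    """Raised when an internal invariant that callers rely on is broken."""


class MemoryGuardError(BitcloseError, RuntimeError):
    """Raised when a mining level would allocate more cells than the configured cap."""


def _as_binary_array(a, name: str = "array") -> np.ndarray:
    """Coerce to an int8 ndarray, rejecting anything that is not exactly 0/1."""
    arr = np.asarray(a)
    if arr.size and not np.isin(arr, (0, 1)).all():
        bad = arr[~np.isin(arr, (0, 1))].ravel()[0]
        raise InvalidInputError(f"{name} must contain only 0/1 entries; found {bad!r}")
    return arr.astype(np.int8, copy=False)


@dataclass
class TransactionDB:
    """An ordered list of transactions (item-label sets) over an item universe.

    ``item_universe`` lists the distinct item labels in first-appearance
    order; the dense column index of a label is its position here.
    Transaction order is preserved from the input.
    """

    transactions: list[frozenset]
    item_universe: list

    def __post_init__(self):
        seen = set()
        for lab in self.item_universe:
            if lab in seen:
                raise InvalidInputError(f"duplicate item label {lab!r} in item universe")
            seen.add(lab)
        for t_idx, t in enumerate(self.transactions):
            missing = set(t) - seen
            if missing:
                raise InvalidInputError(
                    f"transaction {t_idx} contains items outside the universe: {sorted(map(repr, missing))}"
                )

    @classmethod
    def from_iterable(cls, transactions: Iterable[Iterable]) -> "TransactionDB":
        """Build a database, collecting the universe in first-appearance order."""
        universe: list = []
        seen: set = set()
        rows: list[frozenset] = [frozenset(t) for t in transactions]
        # first-appearance order over transactions; sorted within a
        # transaction so set iteration order cannot leak into the column order
        for items in rows:
            for lab in sorted(items, key=_label_sort_key):
                if lab not in seen:
                    seen.add(lab)
                    universe.append(lab)
        return cls(rows, universe)

    def to_bittable(self) -> "BitTable":
        """Materialize the level-0 bit-table (rows = transactions, cols = items)."""
        index = {lab: j for j, lab in enumerate(self.item_universe)}
        vals = np.zeros((len(self.transactions), len(self.item_universe)), dtype=np.int8)
        for i, t in enumerate(self.transactions):
            for lab in t:
                vals[i, index[lab]] = 1
        return BitTable(
            values=vals,
            row_ids=np.arange(len(self.transactions)),
            level=0,
            item_labels=list(self.item_universe),
        )


def _label_sort_key(lab):
    # integers sort numerically, everything else by repr; keeps mixed labels total-ordered
    return (0, lab, "") if isinstance(lab, (int, np.integer)) else (1, 0, str(lab))


@dataclass
class BitTable:
    """A level-k occurrence table B^k with original transaction identity.

    ``row_ids`` maps each row back to its 0-based position in the level-0
    table, so rows deleted at intermediate levels (all-zero rows) never lose
    the identity of the survivors.  ``item_labels`` is only meaningful at
    level 0, where columns still correspond to single items.
    """

    values: np.ndarray
    row_ids: np.ndarray
    level: int = 0
    item_labels: Optional[list] = None

    def __post_init__(self):
        self.values = _as_binary_array(self.values, "bit-table")
        if self.values.ndim != 2:
            raise InvalidInputError("bit-table values must be a 2-D matrix")
        self.row_ids = np.asarray(self.row_ids, dtype=np.int64)
        if self.row_ids.shape != (self.values.shape[0],):
            raise InvalidInputError("row_ids length must equal the number of rows")
        if self.row_ids.size and np.any(np.diff(self.row_ids) <= 0):
            raise InvalidInputError("row_ids must be strictly increasing")
        if self.item_labels is not None and len(self.item_labels) != self.values.shape[1]:
            raise InvalidInputError("item_labels length must equal the number of columns")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def column(self, j: int) -> np.ndarray:
        return self.values[:, j]

    def label_of(self, j: int):
        """Original label of column j (level 0 only); falls back to the index."""
        return self.item_labels[j] if self.item_labels is not None else j

    @classmethod
    def from_dense(cls, values, item_labels: Optional[Sequence] = None) -> "BitTable":
        vals = _as_binary_array(values, "matrix")
        if vals.ndim != 2:
            raise InvalidInputError("expected a 2-D matrix")
        return cls(
            values=vals,
            row_ids=np.arange(vals.shape[0]),
            level=0,
            item_labels=list(item_labels) if item_labels is not None else None,
        )


@dataclass
class SupportMatrix:
    """The symmetric pairwise-support matrix S = Bᵀ B of a bit-table.

    Entry (i, j) is the number of rows where columns i and j are both 1;
    the diagonal carries the individual column supports.
    """

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise InvalidInputError("support matrix must be square")
        if not np.array_equal(self.values, self.values.T):
            raise ContractViolationError("support matrix must be symmetric")

    def support(self, i: int, j: Optional[int] = None) -> int:
        return int(self.values[i, i if j is None else j])


@dataclass
class IndexTable:
    """The pointer table L^k: one strictly increasing k-tuple of original item
    indices per column of the paired bit-table, kept in lexicographic order."""

    rows: list[tuple[int, ...]]

    def __post_init__(self):
        for r in self.rows:
            if any(a >= b for a, b in zip(r, r[1:])):
                raise ContractViolationError(f"index tuple {r} is not strictly increasing")
        if any(a >= b for a, b in zip(self.rows, self.rows[1:])):
            raise ContractViolationError("index table rows must be in strictly increasing lexicographic order")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def level(self) -> int:
        return len(self.rows[0]) if self.rows else 0


@dataclass(frozen=True)
class Itemset:
    """An itemset with its exact support and, optionally, its supporting rows."""

    items: tuple
    support: int
    rows: Optional[frozenset] = None

    def __post_init__(self):
        if not self.items:
            raise InvalidInputError("itemset must be non-empty")
        if self.rows is not None and len(self.rows) != self.support:
            raise ContractViolationError(
                f"support {self.support} disagrees with |rows| = {len(self.rows)}"
            )

    @property
    def size(self) -> int:
        return len(self.items)


@dataclass(frozen=True)
class Bicluster:
    """An inclusion-maximal all-ones submatrix, as (row set, column set)."""

    row_set: frozenset
    col_set: frozenset


@dataclass
class MiningConfig:
    """Mining parameters.

    minsupp
        Minimum support as an absolute transaction count (>= 1).
    min_items
        Minimum itemset size reported by closed extraction (>= 1).
    max_level
        Optional cap on itemset size; mining stops after this level.
    use_subset_filter
        Apply the downward-closure filter at join time (an optimization
        that never changes the output; kept togglable for testing).
    delete_zero_rows
        Drop rows whose sum over a level's surviving columns is zero
        (a size optimization that never changes supports).
    cell_cap
        Upper bound on the number of matrix cells any single level may
        allocate (candidate columns or the pairwise-support matrix);
        exceeding it raises MemoryGuardError instead of exhausting memory.
    """

    minsupp: int
    min_items: int = 1
    max_level: Optional[int] = None
    use_subset_filter: bool = True
    delete_zero_rows: bool = True
    cell_cap: int = 5_000_000

    def __post_init__(self):
        if int(self.minsupp) != self.minsupp or self.minsupp < 1:
            raise ConfigError(f"minsupp must be a positive integer, got {self.minsupp!r}")
        if int(self.min_items) != self.min_items or self.min_items < 1:
            raise ConfigError(f"min_items must be a positive integer, got {self.min_items!r}")
        if self.max_level is not None and self.max_level < 1:
            raise ConfigError(f"max_level must be >= 1, got {self.max_level!r}")
        self.minsupp = int(self.minsupp)
        self.min_items = int(self.min_items)


# ---------------------------------------------------------------------------
# bit-table algebra


def column_support(b) -> int:
    """Support of one occurrence column: the inner product bᵀb.

    On a 0/1 vector this equals the count of ones, i.e. the number of
    transactions containing the column's itemset.
    """
    col = _as_binary_array(b, "column")
    if col.ndim != 1:
        raise InvalidInputError("column must be 1-D")
    return int(col.astype(np.int64) @ col.astype(np.int64))


def pairwise_supports(B: BitTable) -> SupportMatrix:
    """All pairwise joint supports of a table's columns at once: S = Bᵀ B.

    S[i, j] counts the rows where columns i and j are both 1; the diagonal
    is the per-column support.  The product is taken in floating point (BLAS)
    and rounded back to exact integers — counts this size are exactly
    representable.
    """
    V = B.values.astype(np.float64)
    S = np.rint(V.T @ V).astype(np.int64)
    return SupportMatrix(S)


def hadamard_column(b_i, b_j) -> np.ndarray:
    """Element-wise product of two occurrence columns (logical AND).

    The result is the occurrence column of the union of the two itemsets.
    """
    ci = _as_binary_array(b_i, "left column")
    cj = _as_binary_array(b_j, "right column")
    if ci.shape != cj.shape:
        raise InvalidInputError(f"column length mismatch: {ci.shape} vs {cj.shape}")
    return ci * cj
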