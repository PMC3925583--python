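"""Level-wise frequent itemset mining on bit-tables.

The miner is Apriori with all counting replaced by matrix algebra.  At each
level k it holds a table B^(k-1) whose columns are the occurrence vectors of
the frequent (k-1)-itemsets, paired with an index table L^(k-1) of their item
tuples in lexicographic order.  A step then:

1. computes the pairwise-support matrix S = (B^(k-1))ᵀ B^(k-1), whose (i, j)
   entry is the support of the union of itemsets i and j;
2. joins pairs of columns whose tuples share their first k-2 items
   (consecutive tuples with a common prefix form a *block*, so pairs are
   enumerated block-locally), discarding candidates with an infrequent
   (k-1)-subset (downward closure);
3. keeps the candidates whose support — read directly off S — meets minsupp,
   and only then materializes their occurrence columns as Hadamard products;
4. deletes rows that have become all-zero, updating row identities.

Because the support of a joined candidate is exactly the inner product of its
two parent columns, no rescan of the original data is ever needed, and the
expensive full candidate table is never allocated for infrequent candidates.
``join_candidates`` / ``prune`` expose the same step as two explicit phases
(candidate columns first, support filtering second) for inspection and
testing; ``mine_frequent`` uses the fused path above.  Both produce identical
levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    BitTable,
    ConfigError,
    ContractViolationError,
    IndexTable,
    MemoryGuardError,
    MiningConfig,
    column_support,
    hadamard_column,
    pairwise_supports,
)

__all__ = [
    "LevelResult",
    "frequent_singletons",
    "join_candidates",
    "prune",
    "mine_frequent",
]


@dataclass
class LevelResult:
    """All frequent k-itemsets of one level: occurrence table, index table, supports."""

    level: int
    bit_table: BitTable
    index_table: IndexTable
    supports: np.ndarray

    def __post_init__(self):
        self.supports = np.asarray(self.supports, dtype=np.int64)
        if len(self.index_table) != self.bit_table.n_cols:
            raise ContractViolationError("index table row count must match bit-table column count")
        if self.supports.shape != (self.bit_table.n_cols,):
            raise ContractViolationError("one support per column required")

    @property
    def n_itemsets(self) -> int:
        return self.bit_table.n_cols

    def is_empty(self) -> bool:
        return self.bit_table.n_cols == 0

    def rows_of(self, j: int) -> frozenset:
        """Original transaction indices supporting the j-th itemset of this level."""
        col = self.bit_table.values[:, j].astype(bool)
        return frozenset(int(r) for r in self.bit_table.row_ids[col])


def _check_guard(cells: int, cap: int, what: str) -> None:
    if cells > cap:
        raise MemoryGuardError(
            f"{what} would allocate {cells} cells, above the configured cap of {cap}; "
            "raise MiningConfig.cell_cap or increase minsupp"
        )


def frequent_singletons(B0: BitTable, cfg: MiningConfig) -> LevelResult:
    """Level 1: keep the columns of B^0 with support >= minsupp, in index order.

    Rows whose sum over the surviving columns is zero are deleted (they can
    never support any larger frequent itemset), and row identities updated.
    """
    supports = B0.values.astype(np.int64).sum(axis=0)
    keep = np.flatnonzero(supports >= cfg.minsupp)
    vals = B0.values[:, keep]
    row_ids = B0.row_ids
    if cfg.delete_zero_rows and vals.shape[1]:
        nz = vals.sum(axis=1) > 0
        vals = vals[nz]
        row_ids = row_ids[nz]
    elif vals.shape[1] == 0:
        vals = vals[:0]
        row_ids = row_ids[:0]
    return LevelResult(
        level=1,
        bit_table=BitTable(values=vals, row_ids=row_ids, level=1),
        index_table=IndexTable([(int(j),) for j in keep]),
        supports=supports[keep],
    )


def _prefix_blocks(rows: list[tuple[int, ...]]):
    """Yield (start, stop) slices of maximal runs sharing the first k-2 items."""
    k = len(rows[0]) if rows else 0
    i = 0
    while i < len(rows):
        j = i + 1
        while j < len(rows) and rows[j][: k - 1] == rows[i][: k - 1]:
            j += 1
        yield i, j
        i = j


def _subset_ok(tup: tuple[int, ...], frequent: set) -> bool:
    """Downward closure: every (k-1)-subset of the candidate must be frequent."""
    if len(tup) <= 2:
        return True  # the two parents are the only subsets
    return all(tup[:d] + tup[d + 1 :] in frequent for d in range(len(tup) - 2))


def join_candidates(prev: LevelResult, use_subset_filter: bool | None = None):
    """All joinable column pairs of a level, as (k-tuple, Hadamard column) pairs.

    Two (k-1)-itemsets join when their lexicographically ordered first k-2
    items agree and their last items differ; candidates with an infrequent
    (k-1)-subset are discarded before any support is counted.  Output tuples
    are in lexicographic order.
    """
    rows = prev.index_table.rows
    if sorted(rows) != list(rows):
        raise ContractViolationError("index table must be lexicographically sorted before joining")
    if use_subset_filter is None:
        use_subset_filter = True
    frequent = set(rows)
    V = prev.bit_table.values
    out = []
    for lo, hi in _prefix_blocks(rows):
        for i in range(lo, hi):
            for j in range(i + 1, hi):
                tup = rows[i] + (rows[j][-1],)
                if use_subset_filter and not _subset_ok(tup, frequent):
                    continue
                out.append((tup, hadamard_column(V[:, i], V[:, j])))
    return out


def prune(candidates, prev: LevelResult, cfg: MiningConfig) -> LevelResult:
    """Support-filter explicit candidates into the next level.

    Keeps candidate columns with sum >= minsupp, deletes rows that are zero
    across every kept column, and returns the level with its index table in
    lexicographic order.
    """
    k = prev.level + 1
    kept = [(tup, col) for tup, col in candidates if column_support(col) >= cfg.minsupp]
    kept.sort(key=lambda tc: tc[0])
    if not kept:
        empty = np.zeros((0, 0), dtype=np.int8)
        return LevelResult(
            level=k,
            bit_table=BitTable(values=empty, row_ids=np.empty(0, dtype=np.int64), level=k),
            index_table=IndexTable([]),
            supports=np.empty(0, dtype=np.int64),
        )
    vals = np.column_stack([col for _, col in kept]).astype(np.int8)
    supports = vals.astype(np.int64).sum(axis=0)
    row_ids = prev.bit_table.row_ids
    if cfg.delete_zero_rows:
        nz = vals.sum(axis=1) > 0
        vals = vals[nz]
        row_ids = row_ids[nz]
    return LevelResult(
        level=k,
        bit_table=BitTable(values=vals, row_ids=row_ids, level=k),
        index_table=IndexTable([tup for tup, _ in kept]),
        supports=supports,
    )


def _next_level(prev: LevelResult, cfg: MiningConfig) -> LevelResult | None:
    """One fused join+prune step: supports via S = BᵀB, columns only for survivors."""
    rows = prev.index_table.rows
    n = len(rows)
    if n < 2:
        return None
    _check_guard(n * n, cfg.cell_cap, f"pairwise-support matrix at level {prev.level + 1}")
    S = pairwise_supports(prev.bit_table).values
    frequent = set(rows)
    pairs_i: list[int] = []
    pairs_j: list[int] = []
    tuples: list[tuple[int, ...]] = []
    for lo, hi in _prefix_blocks(rows):
        if hi - lo < 2:
            continue
        sub = S[lo:hi, lo:hi]
        ii, jj = np.nonzero(np.triu(sub >= cfg.minsupp, k=1))
        # nonzero is row-major, so (i, j) pairs emerge in lexicographic tuple order
        for a, b in zip(ii, jj):
            tup = rows[lo + a] + (rows[lo + b][-1],)
            if cfg.use_subset_filter and not _subset_ok(tup, frequent):
                continue
            pairs_i.append(lo + a)
            pairs_j.append(lo + b)
            tuples.append(tup)
    if not tuples:
        return None
    N = prev.bit_table.n_rows
    _check_guard(len(tuples) * N, cfg.cell_cap, f"candidate columns at level {prev.level + 1}")
    V = prev.bit_table.values
    vals = V[:, pairs_i] * V[:, pairs_j]
    supports = S[pairs_i, pairs_j].astype(np.int64)
    row_ids = prev.bit_table.row_ids
    if cfg.delete_zero_rows:
        nz = vals.sum(axis=1) > 0
        vals = vals[nz]
        row_ids = row_ids[nz]
    k = prev.level + 1
    return LevelResult(
        level=k,
        bit_table=BitTable(values=vals, row_ids=row_ids, level=k),
        index_table=IndexTable(tuples),
        supports=supports,
    )


def mine_frequent(B0: BitTable, cfg: MiningConfig) -> list[LevelResult]:
    """All frequent itemsets of B^0, level by level.

    Iterates singleton filtering, then fused join/prune steps, until a level
    comes out empty or ``cfg.max_level`` is reached.  The union of index
    tuples over the returned levels is exactly the set of frequent itemsets
    of size >= 1, each with its exact support and (via its column and the
    table's row identities) its supporting-transaction set.
    """
    if not isinstance(cfg, MiningConfig):
        raise ConfigError("cfg must be a MiningConfig")
    levels: list[LevelResult] = []
    lvl = frequent_singletons(B0, cfg)
    while not lvl.is_empty():
        levels.append(lvl)
        if cfg.max_level is not None and lvl.level >= cfg.max_level:
            break
        nxt = _next_level(lvl, cfg)
        if nxt is None or nxt.is_empty():
            break
        lvl = nxt
    return levels
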