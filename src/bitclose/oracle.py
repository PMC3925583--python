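"""Naive reference implementations used as ground truth in tests.

Everything here enumerates all 2^m - 1 non-empty item subsets directly from
the definitions — support by full row scan, closedness against *all* proper
supersets (not just immediate ones), bicluster maximality by explicit
row/column checks.  Rows are packed into integer bitmasks so the enumeration
stays vectorized, but no Apriori pruning, no level structure and no shared
code with the miner is involved.  An item cap keeps the enumeration
tractable; these functions are deliberately naive and intended for small
instances only.
"""

from __future__ import annotations

import numpy as np

from .core import Bicluster, BitTable, InvalidInputError, Itemset, MiningConfig

__all__ = [
    "MAX_ORACLE_ITEMS",
    "enumerate_frequent_bruteforce",
    "enumerate_closed_bruteforce",
    "enumerate_maximal_biclusters_bruteforce",
]

MAX_ORACLE_ITEMS = 24


def _check_width(B0: BitTable) -> None:
    if B0.n_cols > MAX_ORACLE_ITEMS:
        raise InvalidInputError(
            f"brute-force enumeration is capped at {MAX_ORACLE_ITEMS} items; got {B0.n_cols}"
        )


def _row_masks(B0: BitTable) -> np.ndarray:
    """Each transaction as an integer bitmask over the item columns."""
    weights = (1 << np.arange(B0.n_cols, dtype=np.int64))
    return (B0.values.astype(np.int64) @ weights) if B0.n_cols else np.zeros(B0.n_rows, np.int64)


def _all_subset_supports(B0: BitTable) -> np.ndarray:
    """Support of every item subset, indexed by subset bitmask (length 2^m)."""
    m = B0.n_cols
    rows = _row_masks(B0)
    subsets = np.arange(1 << m, dtype=np.int64)
    if B0.n_rows == 0:
        return np.zeros(1 << m, dtype=np.int64)
    contained = (subsets[:, None] & rows[None, :]) == subsets[:, None]
    return contained.sum(axis=1).astype(np.int64)


def _mask_to_tuple(mask: int, m: int) -> tuple[int, ...]:
    return tuple(j for j in range(m) if mask >> j & 1)


def enumerate_frequent_bruteforce(B0: BitTable, cfg: MiningConfig) -> list[Itemset]:
    """Every frequent itemset, by scanning all non-empty subsets.

    Returned in (size ascending, lexicographic) order with supporting rows
    attached, for direct comparison with the miner.
    """
    _check_width(B0)
    m = B0.n_cols
    sup = _all_subset_supports(B0)
    rows = _row_masks(B0)
    out = []
    for mask in range(1, 1 << m):
        if sup[mask] >= cfg.minsupp:
            supporters = frozenset(
                int(r) for r in B0.row_ids[(rows & mask) == mask]
            )
            out.append(Itemset(_mask_to_tuple(mask, m), int(sup[mask]), supporters))
    out.sort(key=lambda it: (it.size, it.items))
    return out


def _max_superset_support(sup: np.ndarray, m: int) -> np.ndarray:
    """best[s] = max support over ALL proper supersets of s (0 if none).

    Computed by a superset sum/max sweep: one pass per item bit propagates the
    maximum down from supersets, so after m passes best[s] covers every
    proper superset transitively.
    """
    idx = np.arange(1 << m)
    # f[s] = max support over every superset of s, s itself included
    f = sup.copy()
    for b in range(m):
        bit = 1 << b
        lo = idx[(idx & bit) == 0]
        f[lo] = np.maximum(f[lo], f[lo | bit])
    # proper supersets only: best over the immediate supersets' f values
    best = np.zeros_like(sup)
    for b in range(m):
        bit = 1 << b
        lo = idx[(idx & bit) == 0]
        best[lo] = np.maximum(best[lo], f[lo | bit])
    return best


def enumerate_closed_bruteforce(B0: BitTable, cfg: MiningConfig) -> list[Itemset]:
    """Frequent itemsets with no proper superset — any, not just immediate —
    of equal support."""
    _check_width(B0)
    m = B0.n_cols
    sup = _all_subset_supports(B0)
    best = _max_superset_support(sup, m)
    out = [
        it
        for it in enumerate_frequent_bruteforce(B0, cfg)
        if best[_tuple_to_mask(it.items)] < it.support
    ]
    return [it for it in out if it.size >= cfg.min_items]


def _tuple_to_mask(items: tuple[int, ...]) -> int:
    mask = 0
    for j in items:
        mask |= 1 << j
    return mask


def enumerate_maximal_biclusters_bruteforce(
    B0: BitTable, min_rows: int = 1, min_cols: int = 1
) -> list[Bicluster]:
    """Every inclusion-maximal all-ones submatrix with at least ``min_rows``
    rows and ``min_cols`` columns, by scanning all column subsets.

    For each subset C the row set is all rows that are 1 on C; the pair is
    kept when it meets the size floors and no row or column can be added.
    Distinct subsets can induce the same bicluster, so results are
    deduplicated.
    """
    _check_width(B0)
    m = B0.n_cols
    rows = _row_masks(B0)
    seen: set[tuple[frozenset, frozenset]] = set()
    out: list[Bicluster] = []
    full = (1 << m) - 1
    for mask in range(1, 1 << m):
        supp = (rows & mask) == mask
        n_sup = int(supp.sum())
        if n_sup < min_rows or n_sup == 0:
            continue
        if bin(mask).count("1") < min_cols:
            continue
        # column-maximality: no item outside C present in every supporting row
        closure = int(np.bitwise_and.reduce(rows[supp])) & full
        if closure != mask:
            continue
        # row-maximality holds by construction: supp is ALL rows containing C
        key = (
            frozenset(int(r) for r in B0.row_ids[supp]),
            frozenset(_mask_to_tuple(mask, m)),
        )
        if key in seen:
            continue
        seen.add(key)
        out.append(Bicluster(row_set=key[0], col_set=key[1]))
    out.sort(key=lambda b: (len(b.col_set), tuple(sorted(b.col_set))))
    return out
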