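"""Closed itemset extraction and the bicluster view.

A frequent itemset J is *closed* when no proper superset has the same
support.  Checking the immediate (|J|+1)-supersets suffices: support is
anti-monotone, so if any proper superset ties J's support, every itemset
between them ties it too — in particular some immediate superset — and that
superset, having support >= minsupp, is itself in the frequent set the miner
produced.

On binary data closed frequent itemsets and inclusion-maximal biclusters are
the same objects: take J's items as the column set and all transactions
containing J as the row set.  Row-maximality is automatic (the row set is
*all* supporting rows); column-maximality is exactly closedness (a column
addable to every supporting row would be an equal-support superset).
"""

from __future__ import annotations

import numpy as np

from .core import (
    Bicluster,
    BitTable,
    ContractViolationError,
    Itemset,
    MiningConfig,
)
from .miner import LevelResult

__all__ = ["extract_closed", "itemset_to_bicluster", "verify_closedness"]


def extract_closed(levels: list[LevelResult], cfg: MiningConfig) -> list[Itemset]:
    """Filter the mined frequent levels down to the closed itemsets.

    For each frequent k-itemset with support s, every one of its (k-1)-subsets
    that also has support s is non-closed; one linear pass over each level
    marks them all.  Output is sorted by (size ascending, lexicographic) and
    restricted to itemsets with at least ``cfg.min_items`` items.  Each
    returned itemset carries its exact supporting-transaction set.
    """
    support_of: list[dict[tuple[int, ...], int]] = []
    for lvl in levels:
        support_of.append(dict(zip(lvl.index_table.rows, (int(s) for s in lvl.supports))))

    non_closed: set[tuple[int, ...]] = set()
    for k_idx in range(1, len(levels)):
        below = support_of[k_idx - 1]
        for tup, s in support_of[k_idx].items():
            for d in range(len(tup)):
                sub = tup[:d] + tup[d + 1 :]
                if below.get(sub) == s:
                    non_closed.add(sub)

    out: list[Itemset] = []
    for lvl in levels:
        if lvl.level < cfg.min_items:
            continue
        for j, tup in enumerate(lvl.index_table.rows):
            if tup in non_closed:
                continue
            out.append(Itemset(items=tup, support=int(lvl.supports[j]), rows=lvl.rows_of(j)))
    # levels are visited in ascending size and each index table is already
    # lexicographic, so the required order falls out for free
    return out


def itemset_to_bicluster(J: Itemset, B0: BitTable) -> Bicluster:
    """The inclusion-maximal bicluster of a closed frequent itemset.

    Columns are J's items; rows are *all* transactions of the level-0 table
    that contain every item of J.
    """
    cols = sorted(J.items)
    mask = B0.values[:, cols].all(axis=1) if cols else np.zeros(B0.n_rows, dtype=bool)
    rows = B0.row_ids[mask]
    if rows.size == 0:
        raise ContractViolationError(f"itemset {J.items} is supported by no transaction")
    return Bicluster(
        row_set=frozenset(int(r) for r in rows),
        col_set=frozenset(int(c) for c in J.items),
    )


def verify_closedness(J: Itemset, B0: BitTable) -> bool:
    """Independent closedness check by direct row scan.

    Recomputes J's support from the level-0 table and tests every single-item
    extension: J is closed iff no extension preserves the support.  Used as a
    cross-check on the miner's output; deliberately does not share any code
    path with :func:`extract_closed`.
    """
    cols = sorted(J.items)
    mask = B0.values[:, cols].all(axis=1)
    support = int(mask.sum())
    if support == 0:
        return False
    others = np.setdiff1d(np.arange(B0.n_cols), cols)
    if others.size == 0:
        return True
    ext_supports = B0.values[mask][:, others].sum(axis=0)
    return not np.any(ext_supports == support)
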