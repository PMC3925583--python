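"""Seeded synthetic binary matrices: uniform-density noise and planted blocks.

``random_binary`` reproduces the kind of unstructured random instance used in
scalability experiments (each entry independently 1 with a fixed density).
``implant_blocks`` overlays all-ones rectangles — planted biclusters — so that
exact-recovery tests have a known answer.  Both are driven by numpy's PCG64
generator and are bitwise-reproducible for a given seed across runs and
platforms.
"""

from __future__ import annotations

import logging

import numpy as np

from .core import BitTable, ConfigError

__all__ = ["random_binary", "implant_blocks"]

log = logging.getLogger(__name__)


def random_binary(n_rows: int, n_cols: int, density: float, seed: int) -> BitTable:
    """A level-0 bit-table with i.i.d. Bernoulli(density) entries.

    The realized ones-fraction is logged; it fluctuates around ``density``
    with binomial standard deviation sqrt(d(1-d)/(rows*cols)).
    """
    if n_rows < 1 or n_cols < 1:
        raise ConfigError(f"matrix dimensions must be positive, got {n_rows}x{n_cols}")
    if not 0.0 <= density <= 1.0:
        raise ConfigError(f"density must be in [0, 1], got {density}")
    rng = np.random.default_rng(seed)
    vals = (rng.random((n_rows, n_cols)) < density).astype(np.int8)
    realized = vals.mean() if vals.size else 0.0
    log.info("random_binary %dx%d target density %.4f realized %.4f", n_rows, n_cols, density, realized)
    return BitTable.from_dense(vals)


def implant_blocks(
    base: BitTable,
    blocks: list[tuple],
    noise: float = 0.0,
    seed: int | None = None,
) -> BitTable:
    """Overlay all-ones blocks on a bit-table, optionally degraded by noise.

    Each block is a (row index set, column index set) pair; its submatrix is
    set to 1, then each block entry independently flipped back to 0 with
    probability ``noise``.  Blocks may overlap.  The base table is not
    modified.
    """
    if not 0.0 <= noise <= 1.0:
        raise ConfigError(f"noise must be in [0, 1], got {noise}")
    vals = base.values.copy()
    rng = np.random.default_rng(seed)
    for rows, cols in blocks:
        r = np.fromiter((int(x) for x in sorted(rows)), dtype=np.int64)
        c = np.fromiter((int(x) for x in sorted(cols)), dtype=np.int64)
        if r.size == 0 or c.size == 0:
            raise ConfigError("blocks must have non-empty row and column sets")
        if r.min() < 0 or r.max() >= base.n_rows or c.min() < 0 or c.max() >= base.n_cols:
            raise ConfigError(
                f"block indices out of range for a {base.n_rows}x{base.n_cols} matrix"
            )
        block = np.ones((r.size, c.size), dtype=np.int8)
        if noise > 0.0:
            keep = rng.random((r.size, c.size)) >= noise
            block = np.where(keep, block, base.values[np.ix_(r, c)]).astype(np.int8)
        vals[np.ix_(r, c)] = block
    return BitTable(values=vals, row_ids=base.row_ids.copy(), level=base.level,
                    item_labels=list(base.item_labels) if base.item_labels is not None else None)
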