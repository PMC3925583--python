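"""Binarization of real-valued expression matrices.

Biclustering on binary data needs a presence/absence call per (gene, sample)
cell.  The standard recipe is a fold-change cutoff: a cell is called
"expressed" when its (ratio-scale) value reaches the cutoff, e.g. a twofold
change.  Two conventions are supported:

* ``mode="up"``   — only up-regulation counts (value >= cutoff);
* ``mode="abs"``  — a twofold change in either direction counts
  (value >= cutoff or value <= 1/cutoff on the ratio scale).

Values may be given as ratios (``scale="ratio"``, all non-negative) or as
log2 ratios (``scale="log2"``), in which case the thresholds become
``value >= log2(cutoff)`` and ``|value| >= log2(cutoff)`` respectively.
Missing entries are conservatively mapped to 0 (no evidence of expression)
and counted in a log message.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import BitTable, ConfigError, InvalidInputError

__all__ = ["ExpressionMatrix", "binarize", "read_expression"]

log = logging.getLogger(__name__)

_MODES = ("up", "abs")
_SCALES = ("ratio", "log2")


@dataclass
class ExpressionMatrix:
    """A genes x samples real-valued matrix with labels; NaN marks missing."""

    values: np.ndarray
    gene_ids: list
    sample_ids: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise InvalidInputError("expression matrix must be 2-D")
        if len(self.gene_ids) != self.values.shape[0]:
            raise InvalidInputError("gene_ids length must match the row count")
        if len(self.sample_ids) != self.values.shape[1]:
            raise InvalidInputError("sample_ids length must match the column count")
        for name, labels in (("gene_ids", self.gene_ids), ("sample_ids", self.sample_ids)):
            if len(set(labels)) != len(labels):
                raise InvalidInputError(f"{name} must be unique")


def read_expression(path, sep: str = ",") -> ExpressionMatrix:
    """Read a dense genes x samples table: header row of sample ids, first
    column of gene ids."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    return ExpressionMatrix(
        values=df.to_numpy(dtype=np.float64),
        gene_ids=list(df.index),
        sample_ids=list(df.columns),
    )


def binarize(
    X: ExpressionMatrix,
    cutoff: float = 2.0,
    mode: str = "up",
    scale: str = "ratio",
) -> BitTable:
    """Threshold an expression matrix into a level-0 bit-table.

    Rows stay genes and columns stay samples; transpose the result's source
    upstream if samples should play the transaction role.
    """
    if cutoff <= 0:
        raise ConfigError(f"cutoff must be positive, got {cutoff}")
    if mode not in _MODES:
        raise ConfigError(f"mode must be one of {_MODES}, got {mode!r}")
    if scale not in _SCALES:
        raise ConfigError(f"scale must be one of {_SCALES}, got {scale!r}")
    V = X.values
    missing = np.isnan(V)
    n_missing = int(missing.sum())
    if n_missing:
        log.warning("binarize: %d missing entries mapped to 0", n_missing)
    if scale == "ratio":
        if np.any(V[~missing] < 0):
            raise InvalidInputError("ratio-scale values must be non-negative")
        if mode == "up":
            bits = V >= cutoff
        else:
            bits = (V >= cutoff) | (V <= 1.0 / cutoff)
    else:
        thr = np.log2(cutoff)
        bits = V >= thr if mode == "up" else np.abs(V) >= thr
    bits = np.where(missing, False, bits)
    return BitTable.from_dense(bits.astype(np.int8), item_labels=list(X.sample_ids))
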