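"""Readers and writers for transaction and binary-matrix formats.

Supported inputs:

* FIMI transaction files — one transaction per line, whitespace-separated
  integer item labels (the community-standard itemset-mining format);
* dense CSV/TSV 0/1 matrices, with optional label header/column;
* MatrixMarket (MTX) sparse coordinate files with all stored values 1.

Transaction row ids in all outputs are 0-based positions in the input;
MatrixMarket coordinates stay 1-based on disk, per that format's convention.
Result files are tab-separated itemset lines plus a JSON sidecar with enough
run metadata (input hash, thresholds, package version) to reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import scipy.io
import scipy.sparse

from .core import (
    Bicluster,
    BitTable,
    InvalidInputError,
    Itemset,
    MiningConfig,
    TransactionDB,
)

__all__ = [
    "read_transactions_fimi",
    "read_binary_matrix",
    "write_binary_matrix",
    "write_results",
    "resolve_minsupp",
    "config_from_args",
]

log = logging.getLogger(__name__)


def read_transactions_fimi(path) -> TransactionDB:
    """Parse a FIMI transaction file, preserving line order.

    Empty lines are kept as empty transactions (they contribute no support);
    duplicate items within a line are collapsed with a warning.
    """
    transactions: list[frozenset] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            items = []
            for tok in tokens:
                try:
                    items.append(int(tok))
                except ValueError:
                    raise InvalidInputError(
                        f"{path}:{lineno}: non-integer item label {tok!r}"
                    ) from None
            if len(set(items)) != len(items):
                log.warning("%s:%d: duplicate items collapsed", path, lineno)
            transactions.append(frozenset(items))
    return TransactionDB.from_iterable(transactions)


def _infer_format(path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = Path(path).suffix.lower()
    return {".csv": "csv", ".tsv": "tsv", ".mtx": "mtx", ".txt": "fimi", ".dat": "fimi"}.get(
        suffix, "csv"
    )


def read_binary_matrix(path, format: str | None = None, labels: bool = False) -> BitTable:
    """Read a 0/1 matrix as a level-0 bit-table.

    ``format`` is one of "csv", "tsv", "mtx" (inferred from the suffix when
    omitted).  With ``labels=True`` a dense file is expected to carry a header
    row of item labels and a first column of row labels (ignored beyond
    ordering).  Any entry outside {0, 1} is an error naming the cell.
    """
    fmt = _infer_format(path, format)
    if fmt == "mtx":
        try:
            mat = scipy.io.mmread(path)
        except ValueError as e:
            raise InvalidInputError(f"malformed MatrixMarket file {path}: {e}") from None
        dense = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat
        )
        return _dense_to_table(dense, path, item_labels=None)
    if fmt not in ("csv", "tsv"):
        raise InvalidInputError(f"unknown matrix format {fmt!r}")
    sep = "," if fmt == "csv" else "\t"
    import pandas as pd

    if labels:
        df = pd.read_csv(path, sep=sep, index_col=0)
        return _dense_to_table(df.to_numpy(), path, item_labels=list(df.columns))
    df = pd.read_csv(path, sep=sep, header=None)
    return _dense_to_table(df.to_numpy(), path, item_labels=None)


def _dense_to_table(dense: np.ndarray, path, item_labels) -> BitTable:
    bad = np.argwhere(~np.isin(dense, (0, 1)))
    if bad.size:
        r, c = bad[0]
        raise InvalidInputError(
            f"{path}: entry at row {r}, column {c} is {dense[r, c]!r}, not 0/1"
        )
    return BitTable.from_dense(dense.astype(np.int8), item_labels=item_labels)


def write_binary_matrix(B: BitTable, path, format: str | None = None) -> None:
    """Write a bit-table as dense CSV/TSV (no labels) or sparse MatrixMarket."""
    fmt = _infer_format(path, format)
    if fmt == "mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(B.values), field="integer")
        return
    if fmt not in ("csv", "tsv"):
        raise InvalidInputError(f"unknown matrix format {fmt!r}")
    sep = "," if fmt == "csv" else "\t"
    np.savetxt(path, B.values, fmt="%d", delimiter=sep)


def _file_sha256(path) -> str | None:
    try:
        h = hashlib.sha256()
        with open(path, "rb") as fh:
            for chunk in iter(lambda: fh.read(65536), b""):
                h.update(chunk)
        return h.hexdigest()
    except OSError:
        return None


def write_results(
    closed: list[Itemset],
    path,
    B0: BitTable | None = None,
    biclusters: list[Bicluster] | None = None,
    emit_rows: bool = False,
    metadata: dict | None = None,
    input_path=None,
) -> None:
    """Write closed itemsets as tab-separated lines, plus a JSON sidecar.

    Each line is ``item labels<TAB>support`` with an optional third column of
    space-separated supporting transaction row ids.  Labels come from the
    level-0 table when given, otherwise the internal item indices are used.
    The sidecar ``<path>.meta.json`` records run metadata (input hash when an
    input path is known, thresholds, package version) so two runs are
    byte-comparable.
    """
    from . import __version__

    def label(j: int):
        return B0.label_of(j) if B0 is not None else j

    path = Path(path)
    with open(path, "w") as fh:
        for it in closed:
            cols = " ".join(str(label(j)) for j in it.items)
            line = f"{cols}\t{it.support}"
            if emit_rows:
                rows = sorted(it.rows) if it.rows is not None else []
                line += "\t" + " ".join(str(r) for r in rows)
            fh.write(line + "\n")
    meta = {
        "n_closed_itemsets": len(closed),
        "version": __version__,
    }
    if input_path is not None:
        meta["input"] = str(input_path)
        digest = _file_sha256(input_path)
        if digest:
            meta["input_sha256"] = digest
    if metadata:
        meta.update(metadata)
    with open(path.with_suffix(path.suffix + ".meta.json"), "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")


def resolve_minsupp(value: float, n_transactions: int) -> int:
    """Absolute minsupp from an int count or a fraction in (0, 1).

    Fractions convert by ceiling(fraction * N) so the threshold is never
    silently rounded down to zero.
    """
    if 0 < value < 1:
        return int(np.ceil(value * n_transactions))
    if value != int(value):
        raise InvalidInputError(f"minsupp must be an integer count or a fraction in (0,1), got {value}")
    return int(value)


def config_from_args(minsupp: float, n_transactions: int, **kwargs) -> MiningConfig:
    return MiningConfig(minsupp=resolve_minsupp(minsupp, n_transactions), **kwargs)
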