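"""Readers and writers: Matrix Market triplets, dense tables, gene lists,
label tables and the packed binary dissimilarity format.

The binary dissimilarity file is: 8 magic bytes, one precision-tag byte
(4 or 8 = bytes per entry), one metric-code byte, an 8-byte little-endian
cell count n, then the n(n−1)/2 packed strict-lower-triangle entries in
row-major order d(i,j), i > j, little-endian.  Round-trips are bit-exact.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .dissim import METRICS, DissimilarityMatrix
from .matrix import ExpressionMatrix

__all__ = [
    "read_mtx",
    "write_mtx",
    "read_dense",
    "read_dissimilarity",
    "write_dissimilarity",
    "read_gene_list",
    "write_gene_list",
    "read_labels",
    "write_labels",
]

MAGIC = b"CPAMDMX1"
_PRECISION_TAG = {"single": 4, "double": 8}
_TAG_PRECISION = {v: k for k, v in _PRECISION_TAG.items()}


class FormatError(ValueError):
    """A file does not conform to its declared on-disk format."""


def _read_id_column(path) -> list[str]:
    """First whitespace/tab-delimited column of a barcodes/features file."""
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0].split(" ")[0])
    return ids


def read_mtx(
    matrix_path,
    barcodes_path,
    features_path,
    orientation: str = "genes_as_rows",
) -> ExpressionMatrix:
    """Load a Matrix Market count matrix with barcode/feature identifiers.

    CellRanger-style exports store genes as rows, which is the default
    ``orientation``; the returned matrix always has cells as rows.
    """
    if orientation not in ("genes_as_rows", "cells_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except ValueError as exc:
        raise FormatError(f"cannot parse Matrix Market file {matrix_path}: {exc}")
    mat = sp.csr_matrix(mat)
    if orientation == "genes_as_rows":
        mat = mat.T.tocsr()
    barcodes = _read_id_column(barcodes_path)
    features = _read_id_column(features_path)
    if mat.shape != (len(barcodes), len(features)):
        raise FormatError(
            f"matrix is {mat.shape[0]} cells × {mat.shape[1]} genes but "
            f"barcodes/features files list {len(barcodes)}/{len(features)} entries"
        )
    return ExpressionMatrix(mat, barcodes, features)


def write_mtx(m: ExpressionMatrix, matrix_path, barcodes_path, features_path) -> None:
    """Write cells-as-columns (CellRanger orientation) .mtx plus id files."""
    scipy.io.mmwrite(str(matrix_path), sp.coo_matrix(m.counts.T))
    Path(barcodes_path).write_text("".join(c + "\n" for c in m.cell_ids))
    Path(features_path).write_text("".join(g + "\n" for g in m.gene_ids))


def read_dense(
    path, delimiter: str = ",", orientation: str = "cells_as_rows"
) -> ExpressionMatrix:
    """Read a dense delimited table with an identifier header row and column."""
    if orientation not in ("genes_as_rows", "cells_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    try:
        df = pd.read_csv(path, sep=delimiter, index_col=0)
    except pd.errors.ParserError as exc:
        raise FormatError(f"cannot parse {path}: {exc}")
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy()
    if np.isnan(values).any():
        bad = df.columns[np.isnan(values).any(axis=0)].tolist()
        raise FormatError(f"non-numeric or missing entries in columns {bad[:5]}")
    row_ids = [str(x) for x in df.index]
    col_ids = [str(x) for x in df.columns]
    if orientation == "genes_as_rows":
        values, row_ids, col_ids = values.T, col_ids, row_ids
    return ExpressionMatrix(sp.csr_matrix(values), row_ids, col_ids)


def write_dissimilarity(d: DissimilarityMatrix, path) -> None:
    with open(path, "wb") as fh:
        fh.write(MAGIC)
        fh.write(struct.pack("<BB", _PRECISION_TAG[d.precision], METRICS.index(d.metric)))
        fh.write(struct.pack("<Q", d.n))
        fh.write(np.ascontiguousarray(d.data).astype("<f4" if d.precision == "single" else "<f8").tobytes())


def read_dissimilarity(path) -> DissimilarityMatrix:
    with open(path, "rb") as fh:
        magic = fh.read(8)
        if magic != MAGIC:
            raise FormatError(f"{path}: bad magic bytes {magic!r}, expected {MAGIC!r}")
        header = fh.read(10)
        if len(header) != 10:
            raise FormatError(f"{path}: truncated header")
        tag, metric_code, n = struct.unpack("<BBQ", header)
        if tag not in _TAG_PRECISION:
            raise FormatError(f"{path}: unknown precision tag {tag}")
        if metric_code >= len(METRICS):
            raise FormatError(f"{path}: unknown metric code {metric_code}")
        npairs = n * (n - 1) // 2
        payload = fh.read()
    expected = npairs * tag
    if len(payload) != expected:
        raise FormatError(
            f"{path}: truncated payload, expected {expected} bytes, found {len(payload)}"
        )
    data = np.frombuffer(payload, dtype="<f4" if tag == 4 else "<f8").copy()
    return DissimilarityMatrix(int(n), METRICS[metric_code], _TAG_PRECISION[tag], data)


def read_gene_list(path) -> list[str]:
    """Plain-text gene list, one symbol per line; blank lines ignored."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes, path) -> None:
    Path(path).write_text("".join(str(g) + "\n" for g in genes))


def read_labels(path) -> pd.Series:
    """Two-column TSV (cell_id, cluster) → Series indexed by cell id."""
    df = pd.read_csv(path, sep="\t", header=0, dtype={0: str})
    if df.shape[1] != 2:
        raise FormatError(f"{path}: expected two columns (cell_id, cluster)")
    return pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0], name="cluster")


def write_labels(cell_ids, labels, path) -> None:
    pd.DataFrame({"cell_id": list(cell_ids), "cluster": np.asarray(labels)}).to_csv(
        path, sep="\t", index=False
    )
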