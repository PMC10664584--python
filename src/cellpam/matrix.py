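"""Core in-memory containers: the cell×gene count matrix and sample metadata.

The expression matrix is held cells-as-rows in CSR form so that per-cell
operations (library-size normalisation, pairwise dissimilarities) touch only
stored entries.  Identifier order is load-bearing: cluster labels, silhouette
values and abundance counts produced downstream all refer to the row/column
order fixed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["ExpressionMatrix", "SampleMetadata"]


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(x) for x in ids]
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dups = sorted({x for x in ids if x in seen or seen.add(x)})
        raise ValueError(f"duplicate {what} identifiers: {dups[:5]}")
    return ids


@dataclass
class ExpressionMatrix:
    """A cell×gene matrix of non-negative expression values.

    Parameters
    ----------
    counts
        ``(n_cells, n_genes)`` matrix; raw counts are integers, normalised
        values are reals.  Stored as CSR; dense input is converted.
    cell_ids, gene_ids
        Unique identifiers for rows and columns.
    sample_of_cell
        Per-cell sample identifier (optional; required for abundance
        analysis).
    """

    counts: sp.csr_matrix
    cell_ids: list[str]
    gene_ids: list[str]
    sample_of_cell: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        self.counts = self.counts.tocsr()
        self.cell_ids = _check_unique(self.cell_ids, "cell")
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        n, p = self.counts.shape
        if n != len(self.cell_ids) or p != len(self.gene_ids):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cell_ids)} cells × {len(self.gene_ids)} genes"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("expression matrix contains negative entries")
        if self.sample_of_cell is not None:
            self.sample_of_cell = np.asarray(self.sample_of_cell, dtype=object)
            if self.sample_of_cell.shape != (n,):
                raise ValueError("sample_of_cell must have one entry per cell")

    # ------------------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def cell_totals(self) -> np.ndarray:
        """Total counts per cell (library sizes)."""
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def genes_detected(self) -> np.ndarray:
        """Number of genes with a nonzero entry, per cell."""
        return np.diff(self.counts.indptr)

    def subset_cells(self, idx: np.ndarray) -> "ExpressionMatrix":
        idx = np.asarray(idx)
        return ExpressionMatrix(
            self.counts[idx],
            [self.cell_ids[i] for i in idx],
            list(self.gene_ids),
            None if self.sample_of_cell is None else self.sample_of_cell[idx],
        )

    def subset_genes(self, idx: np.ndarray) -> "ExpressionMatrix":
        idx = np.asarray(idx)
        return ExpressionMatrix(
            self.counts[:, idx].tocsr(),
            list(self.cell_ids),
            [self.gene_ids[i] for i in idx],
            self.sample_of_cell,
        )

    def to_dense(self) -> np.ndarray:
        return self.counts.toarray()


class SampleMetadata:
    """Per-sample phenotypes: cycle day, the day≤20 split, and phase.

    ``time2`` is a binary indicator that is 0 when the menstrual-cycle day is
    at most 20 and 1 otherwise; when a ``day`` column is present and ``time2``
    is absent it is derived, and when both are present consistency is
    enforced.  ``phase`` is an arbitrary categorical (canonically coded 3 =
    late proliferative, 4 = early/mid secretory, 5 = late secretory).
    """

    DAY_SPLIT = 20

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        if "sample_id" in frame.columns:
            frame = frame.set_index(frame["sample_id"].astype(str)).drop(
                columns="sample_id"
            )
        frame.index = frame.index.astype(str)
        if frame.index.has_duplicates:
            raise ValueError("duplicate sample_id in metadata")
        if "day" in frame.columns:
            derived = (
                pd.to_numeric(frame["day"], errors="coerce") > self.DAY_SPLIT
            ).astype(int)
            derived[frame["day"].isna()] = -1
            if "time2" in frame.columns:
                known = derived >= 0
                if not (frame.loc[known, "time2"].astype(int) == derived[known]).all():
                    raise ValueError(
                        "time2 inconsistent with day: time2 must be 0 iff day <= 20"
                    )
            else:
                if (derived < 0).any():
                    raise ValueError("cannot derive time2: missing day values")
                frame["time2"] = derived
        self.frame = frame

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def __len__(self) -> int:
        return len(self.frame)

    def __repr__(self) -> str:  # pragma: no cover
        return f"SampleMetadata({len(self)} samples, columns={list(self.frame.columns)})"

    def require(self, column: str) -> pd.Series:
        if column not in self.frame.columns:
            raise ValueError(f"metadata lacks required column {column!r}")
        return self.frame[column]

    @classmethod
    def from_tsv(cls, path) -> "SampleMetadata":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="sample_id")
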