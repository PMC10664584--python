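"""Pairwise cell dissimilarities in packed strict-lower-triangular storage.

Three dissimilarities are supported: Manhattan (L1), Euclidean (L2) and the
Pearson dissimilarity 1 − |r|.  The kernels walk the CSR structure of the
expression matrix so that components that are zero in both cells cost
nothing; components zero in exactly one cell reduce to a one-sided term.
Accumulation is always in double precision; only the *storage* of the result
is single or double, which is where the memory goes for large n (the packed
payload is exactly n(n−1)/2 entries).

Pair (i, j) with i > j lives at packed index i(i−1)/2 + j.  Parallel
execution splits the packed index range into ``workers`` contiguous chunks of
equal size (±1), so every worker computes the same number of pairs and the
result is bit-identical for any worker count.
"""

from __future__ import annotations

import warnings
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from numba import njit

from .matrix import ExpressionMatrix

__all__ = [
    "DissimilarityMatrix",
    "packed_index",
    "packed_bytes",
    "compute_dissimilarity",
    "dense_reference",
    "METRICS",
]

METRICS = ("L1", "L2", "Pearson")
_ITEMSIZE = {"single": 4, "double": 8}
_DTYPE = {"single": np.float32, "double": np.float64}


def packed_index(i: int, j: int, n: int) -> int:
    """Packed position of pair (i, j), a bijection onto [0, n(n−1)/2).

    Requires 0 ≤ j < i < n; the diagonal is not stored.
    """
    if not (0 <= j < i < n):
        raise ValueError(f"need 0 <= j < i < n, got i={i}, j={j}, n={n}")
    return i * (i - 1) // 2 + j


def packed_bytes(n: int, precision: str = "single") -> int:
    """Bytes occupied by the packed payload for n cells (computed, not allocated)."""
    if n < 0:
        raise ValueError("n must be non-negative")
    return n * (n - 1) // 2 * _ITEMSIZE[precision]


@dataclass
class DissimilarityMatrix:
    """Packed strict-lower-triangular pairwise dissimilarities.

    ``data[i(i−1)/2 + j]`` holds d(i, j) for i > j; d(i, i) = 0 is implicit
    and the accessor is symmetric.
    """

    n: int
    metric: str
    precision: str
    data: np.ndarray

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}, got {self.metric!r}")
        if self.precision not in _ITEMSIZE:
            raise ValueError("precision must be 'single' or 'double'")
        expect = self.n * (self.n - 1) // 2
        self.data = np.asarray(self.data, dtype=_DTYPE[self.precision])
        if self.data.shape != (expect,):
            raise ValueError(
                f"packed payload has {self.data.shape} entries, expected ({expect},)"
            )

    # ------------------------------------------------------------------
    @property
    def nbytes(self) -> int:
        return self.data.nbytes

    def value(self, i: int, j: int) -> float:
        if i == j:
            return 0.0
        if i < j:
            i, j = j, i
        return float(self.data[packed_index(i, j, self.n)])

    def row(self, i: int) -> np.ndarray:
        """Full row i of the implied square matrix, as float64."""
        n = self.n
        out = np.empty(n, dtype=np.float64)
        out[i] = 0.0
        lo = i * (i - 1) // 2
        out[:i] = self.data[lo : lo + i]
        if i + 1 < n:
            jj = np.arange(i + 1, n, dtype=np.int64)
            out[i + 1 :] = self.data[jj * (jj - 1) // 2 + i]
        return out

    def rows(self, idx) -> np.ndarray:
        """Dense block of rows ``idx`` (len(idx) × n), float64."""
        idx = np.asarray(idx)
        out = np.empty((len(idx), self.n), dtype=np.float64)
        for r, i in enumerate(idx):
            out[r] = self.row(int(i))
        return out

    def to_square(self) -> np.ndarray:
        """Materialise the full symmetric n×n matrix (float64)."""
        out = np.zeros((self.n, self.n), dtype=np.float64)
        ii, jj = np.tril_indices(self.n, k=-1)
        out[ii, jj] = self.data
        out[jj, ii] = self.data
        return out

    def submatrix(self, keep) -> "DissimilarityMatrix":
        """Packed matrix restricted to cells ``keep`` (order preserved).

        Entries are copied, never recomputed, so survivor dissimilarities are
        exact.
        """
        keep = np.asarray(keep, dtype=np.int64)
        m = len(keep)
        new_i, new_j = np.tril_indices(m, k=-1)
        oi = keep[new_i]
        oj = keep[new_j]
        hi = np.maximum(oi, oj)
        lo = np.minimum(oi, oj)
        data = self.data[hi * (hi - 1) // 2 + lo]
        return DissimilarityMatrix(m, self.metric, self.precision, data.copy())

    @classmethod
    def from_square(
        cls, square: np.ndarray, metric: str = "L2", precision: str = "double"
    ) -> "DissimilarityMatrix":
        square = np.asarray(square, dtype=np.float64)
        n = square.shape[0]
        if square.shape != (n, n):
            raise ValueError("square matrix required")
        if not np.allclose(square, square.T):
            raise ValueError("dissimilarity matrix must be symmetric")
        ii, jj = np.tril_indices(n, k=-1)
        return cls(n, metric, precision, square[ii, jj].astype(_DTYPE[precision]))


# ----------------------------------------------------------------------
# numba kernels: sparse (CSR) and dense reference, same accumulation order
# ----------------------------------------------------------------------


@njit(cache=True, inline="always")
def _pair_from_packed(t):
    # invert t = i(i-1)/2 + j; float sqrt then integer fix-up
    i = int((1.0 + np.sqrt(1.0 + 8.0 * t)) / 2.0)
    while i * (i - 1) // 2 > t:
        i -= 1
    while (i + 1) * i // 2 <= t:
        i += 1
    j = t - i * (i - 1) // 2
    return i, j


@njit(cache=True, inline="always")
def _l1_pair(indptr, indices, data, i, j):
    a, a_end = indptr[i], indptr[i + 1]
    b, b_end = indptr[j], indptr[j + 1]
    acc = 0.0
    while a < a_end and b < b_end:
        ga, gb = indices[a], indices[b]
        if ga == gb:
            acc += abs(data[a] - data[b])
            a += 1
            b += 1
        elif ga < gb:
            acc += abs(data[a])
            a += 1
        else:
            acc += abs(data[b])
            b += 1
    while a < a_end:
        acc += abs(data[a])
        a += 1
    while b < b_end:
        acc += abs(data[b])
        b += 1
    return acc


@njit(cache=True, inline="always")
def _l2_pair(indptr, indices, data, i, j):
    a, a_end = indptr[i], indptr[i + 1]
    b, b_end = indptr[j], indptr[j + 1]
    acc = 0.0
    while a < a_end and b < b_end:
        ga, gb = indices[a], indices[b]
        if ga == gb:
            diff = data[a] - data[b]
            acc += diff * diff
            a += 1
            b += 1
        elif ga < gb:
            acc += data[a] * data[a]
            a += 1
        else:
            acc += data[b] * data[b]
            b += 1
    while a < a_end:
        acc += data[a] * data[a]
        a += 1
    while b < b_end:
        acc += data[b] * data[b]
        b += 1
    return np.sqrt(acc)


@njit(cache=True, inline="always")
def _dot_pair(indptr, indices, data, i, j):
    # components zero in either cell contribute nothing to the dot product
    a, a_end = indptr[i], indptr[i + 1]
    b, b_end = indptr[j], indptr[j + 1]
    acc = 0.0
    while a < a_end and b < b_end:
        ga, gb = indices[a], indices[b]
        if ga == gb:
            acc += data[a] * data[b]
            a += 1
            b += 1
        elif ga < gb:
            a += 1
        else:
            b += 1
    return acc


@njit(cache=True, inline="always")
def _pearson_from_stats(dot, p, mi, mj, si, sj, const_i, const_j):
    if const_i or const_j:
        if const_i and const_j and mi == mj:
            return 0.0
        return 1.0
    r = (dot - p * mi * mj) / (p * si * sj)
    if r > 1.0:
        r = 1.0
    elif r < -1.0:
        r = -1.0
    d = 1.0 - abs(r)
    if d < 0.0:
        d = 0.0
    return d


@njit(cache=True, nogil=True)
def _sparse_chunk(
    indptr, indices, data, metric_code, p, mean, std, const, out, lo, hi
):
    for t in range(lo, hi):
        i, j = _pair_from_packed(t)
        if metric_code == 0:
            out[t] = _l1_pair(indptr, indices, data, i, j)
        elif metric_code == 1:
            out[t] = _l2_pair(indptr, indices, data, i, j)
        else:
            dot = _dot_pair(indptr, indices, data, i, j)
            out[t] = _pearson_from_stats(
                dot, p, mean[i], mean[j], std[i], std[j], const[i], const[j]
            )


@njit(cache=True, nogil=True)
def _dense_chunk(X, metric_code, mean, std, const, out, lo, hi):
    p = X.shape[1]
    for t in range(lo, hi):
        i, j = _pair_from_packed(t)
        if metric_code == 0:
            acc = 0.0
            for g in range(p):
                acc += abs(X[i, g] - X[j, g])
            out[t] = acc
        elif metric_code == 1:
            acc = 0.0
            for g in range(p):
                diff = X[i, g] - X[j, g]
                acc += diff * diff
            out[t] = np.sqrt(acc)
        else:
            dot = 0.0
            for g in range(p):
                dot += X[i, g] * X[j, g]
            out[t] = _pearson_from_stats(
                dot, p, mean[i], mean[j], std[i], std[j], const[i], const[j]
            )


def _row_stats(X: sp.csr_matrix):
    """Per-row mean, population s.d. and constant-row flags for Pearson."""
    n, p = X.shape
    s = np.asarray(X.sum(axis=1)).ravel()
    ss = np.asarray(X.multiply(X).sum(axis=1)).ravel()
    mean = s / p
    var = ss / p - mean * mean
    nnz = np.diff(X.indptr)
    const = np.zeros(n, dtype=np.bool_)
    const[nnz == 0] = True
    full = np.flatnonzero(nnz == p)
    for i in full:
        row = X.data[X.indptr[i] : X.indptr[i + 1]]
        if row.size and row.min() == row.max():
            const[i] = True
    var = np.maximum(var, 0.0)
    std = np.sqrt(var)
    std[const] = 0.0
    return mean, std, const


def _chunk_bounds(npairs: int, workers: int) -> list[tuple[int, int]]:
    """Split [0, npairs) into `workers` contiguous chunks of equal size (±1)."""
    base, rem = divmod(npairs, workers)
    bounds, lo = [], 0
    for w in range(workers):
        hi = lo + base + (1 if w < rem else 0)
        bounds.append((lo, hi))
        lo = hi
    return bounds


def _as_csr(m) -> sp.csr_matrix:
    if isinstance(m, ExpressionMatrix):
        m = m.counts
    if not sp.issparse(m):
        m = sp.csr_matrix(np.asarray(m, dtype=np.float64))
    m = m.tocsr().astype(np.float64)
    m.sort_indices()
    return m


def compute_dissimilarity(
    m,
    metric: str = "L2",
    precision: str = "double",
    workers: int = 1,
) -> DissimilarityMatrix:
    """All-pairs dissimilarity matrix for the cells (rows) of ``m``.

    Parameters
    ----------
    m
        :class:`~cellpam.matrix.ExpressionMatrix`, sparse matrix or dense
        array with cells as rows.
    metric
        ``"L1"`` (Manhattan), ``"L2"`` (Euclidean) or ``"Pearson"``
        (1 − |r|, bounded in [0, 1]).
    precision
        Storage precision of the packed result, ``"single"`` (4 bytes/entry)
        or ``"double"`` (8); arithmetic is always double.
    workers
        Number of threads; the pair list is divided into equal contiguous
        chunks and the result does not depend on this value.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")
    if precision not in _ITEMSIZE:
        raise ValueError("precision must be 'single' or 'double'")
    if workers < 1:
        raise ValueError("workers must be >= 1")
    X = _as_csr(m)
    n, p = X.shape
    if n < 2:
        raise ValueError(f"need at least 2 cells, got {n}")
    code = METRICS.index(metric)
    mean, std, const = _row_stats(X)
    if metric == "Pearson" and const.any():
        warnings.warn(
            f"{int(const.sum())} constant cell(s): Pearson correlation is "
            "undefined; using d=1 (d=0 against an identical constant cell)",
            RuntimeWarning,
            stacklevel=2,
        )
    npairs = n * (n - 1) // 2
    out = np.empty(npairs, dtype=_DTYPE[precision])
    args = (X.indptr, X.indices, X.data, code, p, mean, std, const, out)
    bounds = _chunk_bounds(npairs, min(workers, max(npairs, 1)))
    if len(bounds) == 1:
        _sparse_chunk(*args, 0, npairs)
    else:
        with ThreadPoolExecutor(max_workers=len(bounds)) as pool:
            futures = [pool.submit(_sparse_chunk, *args, lo, hi) for lo, hi in bounds]
            for f in futures:
                f.result()
    return DissimilarityMatrix(n, metric, precision, out)


def dense_reference(
    m, metric: str = "L2", precision: str = "double"
) -> DissimilarityMatrix:
    """Single-worker dense-loop reference kernel (ignores sparsity).

    Iterates every component of every pair in index order, so it agrees
    bit-for-bit with the sparse-aware kernel at the same storage precision
    (skipped zero components contribute an exact 0.0).
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")
    X = _as_csr(m)
    n = X.shape[0]
    if n < 2:
        raise ValueError(f"need at least 2 cells, got {n}")
    mean, std, const = _row_stats(X)
    npairs = n * (n - 1) // 2
    out = np.empty(npairs, dtype=_DTYPE[precision])
    _dense_chunk(X.toarray(), METRICS.index(metric), mean, std, const, out, 0, npairs)
    return DissimilarityMatrix(n, metric, precision, out)
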