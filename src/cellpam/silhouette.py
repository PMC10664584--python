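"""Silhouette widths over a packed dissimilarity matrix, and the iterative
silhouette-based cell filter.

For cell i in cluster C_I, a(i) is its mean dissimilarity to the other
members of C_I, b(i) the smallest mean dissimilarity to any other cluster,
and s(i) = (b−a)/max(a, b), defined as 0 when C_I is a singleton.  Values
lie in [−1, 1]; the global mean summarises how compact the clustering is.

The filter repeatedly removes the fraction of cells with the lowest
silhouette until a target fraction of the survivors exceeds a threshold,
optionally refreshing the clustering between rounds.
"""

from __future__ import annotations

import math
import warnings
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .base import BaseEstimator
from .dissim import DissimilarityMatrix
from .pam import _as_dissim, pam

__all__ = ["SilhouetteResult", "silhouette", "SilhouetteFilter",
           "SilhouetteFilterResult", "silhouette_filter"]

_CHUNK = 256


@dataclass
class SilhouetteResult:
    s: np.ndarray
    cluster_mean: pd.Series
    global_mean: float


def _factorize(labels):
    labels = np.asarray(labels)
    codes, uniques = pd.factorize(labels, sort=True)
    return codes, uniques


def _silhouette_chunk(D, codes, members, sizes, s, lo, hi):
    idx = np.arange(lo, hi)
    block = D.rows(idx)
    k = len(members)
    sums = np.empty((len(idx), k))
    for j in range(k):
        sums[:, j] = block[:, members[j]].sum(axis=1)
    own = codes[idx]
    rows = np.arange(len(idx))
    own_size = sizes[own]
    with np.errstate(invalid="ignore", divide="ignore"):
        a = sums[rows, own] / (own_size - 1)
        means = sums / sizes
        means[rows, own] = np.inf
        b = means.min(axis=1)
        val = (b - a) / np.maximum(a, b)
    val[own_size == 1] = 0.0
    val[~np.isfinite(val)] = 0.0  # a = b = 0: point sits exactly on both
    s[idx] = val


def silhouette(D, labels, workers: int = 1) -> SilhouetteResult:
    """Per-cell silhouette widths s(i) for a labelled dissimilarity matrix.

    ``labels`` may be any hashable values; singleton clusters score 0, and a
    single-cluster labelling yields all zeros with a warning.  The result is
    independent of ``workers``.
    """
    D = _as_dissim(D)
    codes, uniques = _factorize(labels)
    if len(codes) != D.n:
        raise ValueError(f"labels length {len(codes)} != n cells {D.n}")
    if workers < 1:
        raise ValueError("workers must be >= 1")
    k = len(uniques)
    if k < 2:
        warnings.warn(
            "single cluster: all silhouette values are 0", RuntimeWarning,
            stacklevel=2,
        )
        s = np.zeros(D.n)
    else:
        members = [np.flatnonzero(codes == j) for j in range(k)]
        sizes = np.array([len(mj) for mj in members], dtype=np.float64)
        s = np.empty(D.n)
        bounds = [
            (lo, min(lo + _CHUNK, D.n)) for lo in range(0, D.n, _CHUNK)
        ]
        if workers == 1 or len(bounds) == 1:
            for lo, hi in bounds:
                _silhouette_chunk(D, codes, members, sizes, s, lo, hi)
        else:
            with ThreadPoolExecutor(max_workers=workers) as pool:
                futures = [
                    pool.submit(_silhouette_chunk, D, codes, members, sizes, s, lo, hi)
                    for lo, hi in bounds
                ]
                for f in futures:
                    f.result()
    cluster_mean = pd.Series(
        [s[codes == j].mean() for j in range(k)], index=list(uniques)
    )
    return SilhouetteResult(s, cluster_mean, float(s.mean()))


@dataclass
class SilhouetteFilterResult:
    kept: np.ndarray          # surviving cell indices, original coordinates
    labels: np.ndarray        # labels of the survivors
    met: bool                 # target criterion reached
    n_rounds: int
    history: list = field(default_factory=list)  # per-round (n_cells, frac>thr)


class SilhouetteFilter(BaseEstimator):
    """Iterative removal of poorly-silhouetted cells.

    Each round computes silhouettes and stops if at least ``target_frac`` of
    the current cells have s strictly greater than ``threshold``; otherwise
    the ⌊drop_frac·n⌋ (at least 1) lowest-s cells are removed — boundary
    ties resolved toward the lower cell index — and, when ``recluster_k`` is
    set, PAM is re-run on the surviving submatrix.  Pairwise dissimilarities
    of survivors are extracted, never recomputed.

    Attributes: ``kept_indices_``, ``labels_``, ``met_``, ``n_rounds_``,
    ``history_``.
    """

    def __init__(
        self,
        drop_frac: float = 0.15,
        target_frac: float = 0.60,
        threshold: float = 0.7,
        recluster_k: int | None = None,
        max_iter: int = 1000,
        workers: int = 1,
    ):
        self.drop_frac = drop_frac
        self.target_frac = target_frac
        self.threshold = threshold
        self.recluster_k = recluster_k
        self.max_iter = max_iter
        self.workers = workers

    def fit(self, D, labels) -> "SilhouetteFilter":
        if not 0.0 < self.drop_frac < 1.0:
            raise ValueError("drop_frac must be in (0, 1)")
        D = _as_dissim(D)
        labels = np.asarray(labels)
        if len(labels) != D.n:
            raise ValueError("labels length must equal the number of cells")
        kept = np.arange(D.n)
        D_cur, labels_cur = D, labels.copy()
        history: list[tuple[int, float]] = []
        met = False
        rounds = 0
        while True:
            res = silhouette(D_cur, labels_cur, workers=self.workers)
            frac = float(np.mean(res.s > self.threshold))
            history.append((len(kept), frac))
            if frac >= self.target_frac:
                met = True
                break
            n_cur = len(kept)
            n_drop = max(1, math.floor(self.drop_frac * n_cur))
            if n_drop >= n_cur:
                warnings.warn(
                    "cells exhausted before the silhouette criterion was met",
                    RuntimeWarning, stacklevel=2,
                )
                break
            order = np.argsort(res.s, kind="stable")  # ties -> lower index
            survivors = np.sort(order[n_drop:])
            kept = kept[survivors]
            D_cur = D_cur.submatrix(survivors)
            labels_cur = labels_cur[survivors]
            rounds += 1
            if self.recluster_k is not None:
                k = min(self.recluster_k, len(kept))
                labels_cur = pam(D_cur, k, max_iter=self.max_iter).labels
        self.kept_indices_ = kept
        self.labels_ = labels_cur
        self.met_ = met
        self.n_rounds_ = rounds
        self.history_ = history
        return self


def silhouette_filter(
    D,
    labels,
    drop_frac: float = 0.15,
    target_frac: float = 0.60,
    threshold: float = 0.7,
    recluster_k: int | None = None,
    workers: int = 1,
) -> SilhouetteFilterResult:
    """Functional wrapper around :class:`SilhouetteFilter`."""
    f = SilhouetteFilter(
        drop_frac=drop_frac,
        target_frac=target_frac,
        threshold=threshold,
        recluster_k=recluster_k,
        workers=workers,
    ).fit(D, labels)
    return SilhouetteFilterResult(
        f.kept_indices_, f.labels_, f.met_, f.n_rounds_, f.history_
    )
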