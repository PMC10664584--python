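"""PAM (k-medoids) clustering over a precomputed dissimilarity matrix.

The objective is TD = Σᵢ d(xᵢ, nearest medoid).  Initialisation is greedy
BUILD (or the subsampled LAB variant); the swap phase is FASTPAM1, which
evaluates every (candidate, medoid) exchange in O(n) per candidate using two
cached arrays — each point's distance to its nearest and to its
second-nearest medoid — and deterministically applies the single swap with
the largest strict TD reduction until none remains.

With BUILD initialisation the whole procedure (PAM-BS) is deterministic;
every tie (initial medoid, best swap, nearest medoid) is broken toward the
lowest index.  The dissimilarity matrix stays in packed storage: dense rows
are materialised in fixed-size chunks only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .base import BaseEstimator
from .dissim import DissimilarityMatrix, compute_dissimilarity

__all__ = ["PamResult", "PAM", "pam", "pam_build", "pam_lab", "pam_fastpam1",
           "assign_labels", "swap_delta_td"]

_CHUNK = 256


@dataclass
class PamResult:
    """Outcome of a PAM run.

    ``td_trace`` holds TD after initialisation and after each applied swap;
    it is strictly decreasing.  ``converged`` is False only when ``max_iter``
    stopped the swap phase early.
    """

    medoids: np.ndarray
    labels: np.ndarray
    td: float
    iterations: int
    td_trace: list = field(default_factory=list)
    converged: bool = True


def _as_dissim(D) -> DissimilarityMatrix:
    if isinstance(D, DissimilarityMatrix):
        return D
    return DissimilarityMatrix.from_square(np.asarray(D, dtype=np.float64))


def _check_medoids(medoids, n: int) -> np.ndarray:
    medoids = np.asarray(medoids, dtype=np.int64)
    if medoids.ndim != 1 or len(medoids) == 0:
        raise ValueError("medoids must be a non-empty 1-D index list")
    if len(np.unique(medoids)) != len(medoids):
        raise ValueError("medoid indices must be distinct")
    if medoids.min() < 0 or medoids.max() >= n:
        raise ValueError(f"medoid indices out of range for n={n}")
    return medoids.copy()


def _nearest_cache(D: DissimilarityMatrix, medoids: np.ndarray):
    """labels, d_nearest, d_second for the current medoid set."""
    block = D.rows(medoids)  # k × n
    labels = np.argmin(block, axis=0)  # ties -> lowest medoid position
    cols = np.arange(D.n)
    d_nearest = block[labels, cols]
    if len(medoids) == 1:
        d_second = np.full(D.n, np.inf)
    else:
        block[labels, cols] = np.inf
        d_second = block.min(axis=0)
    return labels, d_nearest, d_second


def assign_labels(D, medoids) -> np.ndarray:
    """Nearest-medoid assignment; equidistant points go to the lower medoid
    position, and medoids label their own cluster."""
    D = _as_dissim(D)
    medoids = _check_medoids(medoids, D.n)
    labels, _, _ = _nearest_cache(D, medoids)
    return labels


def pam_build(D, k: int):
    """Greedy BUILD initialisation.

    The first medoid minimises the total distance to all points; each later
    medoid maximises the TD reduction given the current nearest-medoid
    distances.  Returns ``(medoids, d_nearest, td)``; fully deterministic.
    """
    D = _as_dissim(D)
    n = D.n
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n, got k={k}, n={n}")
    # total distance of every point to all others, chunked over rows
    rowsum = np.empty(n)
    for lo in range(0, n, _CHUNK):
        idx = np.arange(lo, min(lo + _CHUNK, n))
        rowsum[idx] = D.rows(idx).sum(axis=1)
    first = int(np.argmin(rowsum))
    medoids = [first]
    d_nearest = D.row(first)
    is_medoid = np.zeros(n, dtype=bool)
    is_medoid[first] = True
    while len(medoids) < k:
        best_gain = np.inf
        best_cand = -1
        for lo in range(0, n, _CHUNK):
            idx = np.arange(lo, min(lo + _CHUNK, n))
            block = D.rows(idx)
            gains = np.minimum(block - d_nearest, 0.0).sum(axis=1)
            gains[is_medoid[idx]] = np.inf
            pos = int(np.argmin(gains))
            if gains[pos] < best_gain:  # strict: keeps lowest index on ties
                best_gain = float(gains[pos])
                best_cand = int(idx[pos])
        medoids.append(best_cand)
        is_medoid[best_cand] = True
        np.minimum(d_nearest, D.row(best_cand), out=d_nearest)
    return np.asarray(medoids, dtype=np.int64), d_nearest, float(d_nearest.sum())


def pam_lab(D, k: int, rng: np.random.Generator):
    """LAB initialisation: BUILD restricted to a fresh random subsample of
    10 + ⌈√n⌉ points per medoid.  Seeded and reproducible."""
    D = _as_dissim(D)
    n = D.n
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n, got k={k}, n={n}")
    subsize = 10 + math.ceil(math.sqrt(n))
    medoids: list[int] = []
    d_nearest = np.full(n, np.inf)
    is_medoid = np.zeros(n, dtype=bool)
    for _ in range(k):
        pool = np.flatnonzero(~is_medoid)
        sample = rng.choice(pool, size=min(subsize, len(pool)), replace=False)
        sample.sort()
        block = D.rows(sample)[:, sample]  # candidate × sample-point distances
        if not medoids:
            gains = block.sum(axis=1)
        else:
            gains = np.minimum(block - d_nearest[sample], 0.0).sum(axis=1)
        chosen = int(sample[int(np.argmin(gains))])
        medoids.append(chosen)
        is_medoid[chosen] = True
        np.minimum(d_nearest, D.row(chosen), out=d_nearest)
    return np.asarray(medoids, dtype=np.int64), d_nearest, float(d_nearest.sum())


def swap_delta_td(D, medoids, labels=None, d_nearest=None, d_second=None) -> np.ndarray:
    """TD change for every (candidate, medoid-position) exchange.

    Returns an (n, k) array where entry (c, i) is the TD change from
    replacing ``medoids[i]`` by point c (negative = improvement); rows of
    current medoids are +inf.  This is the FASTPAM1 bookkeeping: one pass
    over the points per candidate, using the nearest/second-nearest caches.
    """
    D = _as_dissim(D)
    medoids = _check_medoids(medoids, D.n)
    if labels is None or d_nearest is None or d_second is None:
        labels, d_nearest, d_second = _nearest_cache(D, medoids)
    n, k = D.n, len(medoids)
    delta = np.empty((n, k))
    onehot = [np.flatnonzero(labels == i) for i in range(k)]
    for lo in range(0, n, _CHUNK):
        idx = np.arange(lo, min(lo + _CHUNK, n))
        block = D.rows(idx)
        gains = np.minimum(block - d_nearest, 0.0)
        shared = gains.sum(axis=1)
        # correction for points whose nearest medoid is the one removed:
        # they fall back to min(d(·,candidate), d_second)
        adj = np.minimum(block, d_second) - d_nearest - gains
        for i in range(k):
            delta[idx, i] = shared + adj[:, onehot[i]].sum(axis=1)
    delta[medoids, :] = np.inf
    return delta


def pam_fastpam1(D, medoids, max_iter: int = 1000) -> PamResult:
    """FASTPAM1 swap phase from a given medoid set.

    Each iteration evaluates all (candidate, medoid) swaps via
    :func:`swap_delta_td` and applies the single swap with the largest
    strict TD reduction (ties: lowest candidate index, then lowest medoid
    position); stops when no swap strictly reduces TD.
    """
    D = _as_dissim(D)
    medoids = _check_medoids(medoids, D.n)
    labels, d_nearest, d_second = _nearest_cache(D, medoids)
    td = float(d_nearest.sum())
    trace = [td]
    iterations = 0
    converged = False
    while iterations < max_iter:
        delta = swap_delta_td(D, medoids, labels, d_nearest, d_second)
        flat = int(np.argmin(delta))  # row-major: lowest candidate, then medoid
        cand, mpos = divmod(flat, len(medoids))
        if not delta[cand, mpos] < 0.0:
            converged = True
            break
        medoids[mpos] = cand
        labels, d_nearest, d_second = _nearest_cache(D, medoids)
        td = float(d_nearest.sum())
        trace.append(td)
        iterations += 1
    else:
        # max_iter reached; converged only if no improving swap remains
        delta = swap_delta_td(D, medoids, labels, d_nearest, d_second)
        converged = not (delta.min() < 0.0)
    return PamResult(medoids, labels, td, iterations, trace, converged)


def pam(
    D,
    k: int,
    init: str = "build",
    max_iter: int = 1000,
    seed: int | None = None,
) -> PamResult:
    """BUILD (or LAB) initialisation followed by the FASTPAM1 swap phase.

    With ``init="build"`` the run is fully deterministic (PAM-BS); the seed
    is consumed only by LAB.
    """
    D = _as_dissim(D)
    init = init.lower()
    if init == "build":
        medoids, _, _ = pam_build(D, k)
    elif init == "lab":
        medoids, _, _ = pam_lab(D, k, np.random.default_rng(seed))
    else:
        raise ValueError(f"init must be 'build' or 'lab', got {init!r}")
    if k == D.n:
        return PamResult(medoids, assign_labels(D, medoids), 0.0, 0, [0.0], True)
    return pam_fastpam1(D, medoids, max_iter=max_iter)


class PAM(BaseEstimator):
    """k-medoids clustering estimator (PAM-BS: BUILD + FASTPAM1).

    Parameters
    ----------
    n_clusters
        Number of medoids k.
    metric
        ``"precomputed"`` (fit X is a :class:`DissimilarityMatrix` or square
        symmetric array) or one of ``"L1"``, ``"L2"``, ``"Pearson"`` to
        compute the dissimilarity from a cell×gene matrix.
    precision
        Storage precision when the dissimilarity is computed here.
    init
        ``"build"`` (deterministic) or ``"lab"`` (seeded subsampling).
    max_iter
        Swap-phase iteration cap; ``converged_`` reports whether the cap
        was the stopping reason.
    workers
        Threads for the dissimilarity computation (result-invariant).
    random_state
        Seed for LAB initialisation.

    Attributes
    ----------
    medoid_indices_ : ndarray of k distinct point indices
    labels_ : per-point cluster index in [0, k)
    inertia_ : float, the TD objective
    n_iter_ : number of applied swaps
    td_trace_ : TD after initialisation and after each swap
    converged_ : bool
    dissimilarity_ : the DissimilarityMatrix used for the fit
    """

    def __init__(
        self,
        n_clusters: int = 30,
        metric: str = "precomputed",
        precision: str = "double",
        init: str = "build",
        max_iter: int = 1000,
        workers: int = 1,
        random_state: int | None = None,
    ):
        self.n_clusters = n_clusters
        self.metric = metric
        self.precision = precision
        self.init = init
        self.max_iter = max_iter
        self.workers = workers
        self.random_state = random_state

    def fit(self, X, y=None) -> "PAM":
        if self.metric == "precomputed":
            D = _as_dissim(X)
        else:
            D = compute_dissimilarity(
                X, metric=self.metric, precision=self.precision,
                workers=self.workers,
            )
        result = pam(
            D,
            k=self.n_clusters,
            init=self.init,
            max_iter=self.max_iter,
            seed=self.random_state,
        )
        self.dissimilarity_ = D
        self.medoid_indices_ = result.medoids
        self.labels_ = result.labels
        self.inertia_ = result.td
        self.n_iter_ = result.iterations
        self.td_trace_ = result.td_trace
        self.converged_ = result.converged
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_
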