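"""Quality control, per-cell normalisation and highly-variable-gene selection.

Two normalisations feed the dissimilarity step:

* ``rawn`` — each count divided by its cell's total, so every cell becomes a
  composition summing to 1;
* ``log1n`` — the same division applied to log(1 + count) values, i.e. each
  cell's log-counts are rescaled to sum to 1.

Both preserve the sparsity pattern.  HVG selection follows the
variance-stabilising-transform recipe: a trend of log10 variance on log10
mean yields an expected standard deviation per gene, counts are standardised
against it, clipped at √n, and genes are ranked by the variance of the
clipped standardised values.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.sparse as sp
from statsmodels.nonparametric.smoothers_lowess import lowess

from .matrix import ExpressionMatrix

__all__ = [
    "qc_filter",
    "normalize_rawn",
    "normalize_log1n",
    "select_hvg",
    "filter_genes",
]


def qc_filter(
    m: ExpressionMatrix,
    min_counts: int = 2500,
    min_genes: int = 750,
    max_mito_frac: float = 0.25,
    mito_prefix: str = "MT-",
    return_report: bool = False,
):
    """Keep cells with enough counts and genes and a low mitochondrial load.

    A cell survives when its total count is at least ``min_counts``, it has
    at least ``min_genes`` genes with nonzero expression, and its
    mitochondrial fraction (genes whose id starts with ``mito_prefix``,
    case-insensitive) does not exceed ``max_mito_frac``.  The gene set is
    unchanged.  With ``return_report=True`` also returns a dict with the
    number of cells failing each criterion and the number removed.
    """
    totals = m.cell_totals()
    detected = m.genes_detected()
    prefix = mito_prefix.upper()
    mito_mask = np.array([g.upper().startswith(prefix) for g in m.gene_ids])
    if not mito_mask.any():
        warnings.warn(
            f"no genes with prefix {mito_prefix!r}: mitochondrial criterion "
            "passes vacuously",
            RuntimeWarning,
            stacklevel=2,
        )
        mito_frac = np.zeros(m.n_cells)
    else:
        mito_counts = np.asarray(
            m.counts[:, np.flatnonzero(mito_mask)].sum(axis=1)
        ).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 1.0)
    pass_counts = totals >= min_counts
    pass_genes = detected >= min_genes
    pass_mito = mito_frac <= max_mito_frac
    keep = pass_counts & pass_genes & pass_mito
    out = m.subset_cells(np.flatnonzero(keep))
    if return_report:
        report = {
            "n_input": m.n_cells,
            "n_kept": int(keep.sum()),
            "n_removed": int((~keep).sum()),
            "fail_min_counts": int((~pass_counts).sum()),
            "fail_min_genes": int((~pass_genes).sum()),
            "fail_max_mito": int((~pass_mito).sum()),
        }
        return out, report
    return out


def _require_positive_totals(m: ExpressionMatrix, totals: np.ndarray) -> None:
    zero = np.flatnonzero(totals <= 0)
    if zero.size:
        ids = [m.cell_ids[i] for i in zero[:5]]
        raise ValueError(f"cells with zero total count cannot be normalised: {ids}")


def normalize_rawn(m: ExpressionMatrix) -> ExpressionMatrix:
    """Divide each cell's counts by its total; rows sum to 1."""
    totals = m.cell_totals()
    _require_positive_totals(m, totals)
    x = m.counts.astype(np.float64).tocsr()
    x.data /= np.repeat(totals, np.diff(x.indptr))
    return ExpressionMatrix(x, m.cell_ids, m.gene_ids, m.sample_of_cell)


def normalize_log1n(m: ExpressionMatrix) -> ExpressionMatrix:
    """Divide each cell's log(1+count) values by their per-cell total."""
    x = m.counts.astype(np.float64).tocsr()
    x.data = np.log1p(x.data)
    totals = np.asarray(x.sum(axis=1)).ravel()
    _require_positive_totals(m, totals)
    x.data /= np.repeat(totals, np.diff(x.indptr))
    return ExpressionMatrix(x, m.cell_ids, m.gene_ids, m.sample_of_cell)


def _vst_standardized_variance(counts: sp.csr_matrix, span: float) -> np.ndarray:
    """Variance of clipped standardised counts per gene (vst ranking score)."""
    X = counts.tocsc().astype(np.float64)
    n, p = X.shape
    mean = np.asarray(X.mean(axis=0)).ravel()
    sq = X.multiply(X)
    ex2 = np.asarray(sq.mean(axis=0)).ravel()
    var = (ex2 - mean**2) * n / max(n - 1, 1)
    score = np.zeros(p)
    fit_mask = var > 0
    if fit_mask.sum() == 0:
        return score
    log_mean = np.log10(mean[fit_mask])
    log_var = np.log10(var[fit_mask])
    if fit_mask.sum() < 3 or np.ptp(log_mean) == 0:
        exp_sd = np.sqrt(var[fit_mask])  # degenerate trend: each gene its own sd
    else:
        fitted = lowess(
            log_var, log_mean, frac=span, return_sorted=False, it=1
        )
        exp_sd = np.sqrt(10.0**fitted)
    clip = np.sqrt(n)
    idx_fit = np.flatnonzero(fit_mask)
    for pos, g in enumerate(idx_fit):
        sd = exp_sd[pos]
        if sd <= 0 or not np.isfinite(sd):
            continue
        col = X.data[X.indptr[g] : X.indptr[g + 1]]
        mu = mean[g]
        z_nz = np.minimum((col - mu) / sd, clip)
        z0 = min(-mu / sd, clip)
        n0 = n - col.size
        s1 = n0 * z0 + z_nz.sum()
        s2 = n0 * z0 * z0 + (z_nz * z_nz).sum()
        score[g] = (s2 - s1 * s1 / n) / max(n - 1, 1)
    return score


def select_hvg(m: ExpressionMatrix, n_hvg: int, span: float = 0.3) -> list[str]:
    """Rank genes by vst standardised variance and return the top ``n_hvg`` ids.

    Deterministic: ties (and zero-variance genes) keep original gene order.
    """
    if n_hvg > m.n_genes:
        raise ValueError(f"n_hvg={n_hvg} exceeds number of genes ({m.n_genes})")
    if n_hvg < 1:
        raise ValueError("n_hvg must be >= 1")
    score = _vst_standardized_variance(m.counts, span)
    order = np.argsort(-score, kind="stable")
    return [m.gene_ids[i] for i in order[:n_hvg]]


def filter_genes(m: ExpressionMatrix, keep) -> ExpressionMatrix:
    """Column subset in the order of ``keep``; unknown ids raise."""
    keep = [str(g) for g in keep]
    pos = {g: i for i, g in enumerate(m.gene_ids)}
    unknown = [g for g in keep if g not in pos]
    if unknown:
        raise ValueError(f"unknown gene ids: {unknown[:10]}")
    return m.subset_genes(np.array([pos[g] for g in keep], dtype=np.int64))
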