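"""Differential cell abundance with negative-binomial GLMs.

The unit of analysis is the cluster×sample table of cell counts.  For each
cluster, counts across samples are modelled as negative binomial with a log
link and an offset log(total clustered cells per sample), so coefficients
are log-fold changes in the cluster's share of a sample.  Supported designs:

* ``time``  — numeric day of the menstrual cycle;
* ``time2`` — the binary day ≤ 20 vs > 20 split;
* ``phase`` — categorical cycle phase, treatment-coded against the lowest
  level, tested jointly (all phase coefficients zero) or as 1-df pairwise
  level contrasts.

Two tests are provided: a likelihood-ratio chi-square (LRT) against the
nested reduced model, and a quasi-likelihood F-test (QL) in which the
deviance drop is scaled by a squeezed cluster-wise quasi-dispersion — a
deliberately conservative variant.  The NB dispersion φ (variance μ + φμ²)
is estimated by profile maximum likelihood under the full model, either
common to all clusters or per-cluster ("tagwise") shrunk halfway toward the
common value on the log scale.  P-values are Benjamini–Hochberg adjusted
across clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from scipy.optimize import minimize_scalar
from statsmodels.stats.multitest import multipletests

from .base import BaseEstimator
from .matrix import SampleMetadata

__all__ = [
    "AbundanceTable",
    "DAResult",
    "cluster_sample_counts",
    "NBAbundanceGLM",
    "nb_glm_lrt",
    "nb_glm_ql",
    "nb_test_designs",
    "phase_contrasts",
]

_MIN_ALPHA = 1e-6
_MAX_ALPHA = 100.0


@dataclass
class AbundanceTable:
    """Cluster×sample cell counts joined with per-sample phenotypes."""

    counts: pd.DataFrame  # clusters × samples, non-negative integers
    metadata: SampleMetadata

    def __post_init__(self) -> None:
        missing = [s for s in self.counts.columns if str(s) not in
                   set(self.metadata.sample_ids)]
        if missing:
            raise ValueError(f"samples without metadata: {missing[:5]}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative cell counts")

    @property
    def cluster_ids(self) -> list:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.counts.columns]

    def sample_totals(self) -> np.ndarray:
        return self.counts.to_numpy().sum(axis=0)


def cluster_sample_counts(labels, cell_sample_ids, meta: SampleMetadata) -> AbundanceTable:
    """Tally cells into a cluster×sample table.

    Every sample present in ``meta`` gets a column (zero-filled if no cell
    landed there); clusters are the observed label values, sorted.
    """
    labels = np.asarray(labels)
    samples = np.asarray(cell_sample_ids, dtype=object)
    if len(labels) == 0:
        raise ValueError("no labelled cells")
    if len(labels) != len(samples):
        raise ValueError("labels and cell_sample_ids must have equal length")
    known = set(meta.sample_ids)
    unknown = sorted({str(s) for s in samples} - known)
    if unknown:
        raise ValueError(f"cells reference unknown sample ids: {unknown[:5]}")
    df = pd.crosstab(pd.Series(labels, name="cluster"),
                     pd.Series([str(s) for s in samples], name="sample"))
    df = df.reindex(columns=meta.sample_ids, fill_value=0)
    return AbundanceTable(df, meta)


@dataclass
class DAResult:
    """Per-cluster differential-abundance test results.

    ``table`` is indexed by cluster with columns ``estimate`` (log-fold
    change of the tested effect; NaN for multi-df joint tests), per-tested-
    coefficient ``coef_*`` columns, ``dispersion``, ``stat``, ``pvalue`` and
    BH-adjusted ``qvalue``; ``flagged`` marks clusters that could not be fit
    (all-zero counts), reported with p = 1.
    """

    table: pd.DataFrame
    test_kind: str      # "LRT" or "QL"
    design_name: str    # "time", "time2", "phase_joint", "phase_pairwise(A,B)"

    def significant(self, fdr: float = 0.05) -> list:
        return list(self.table.index[self.table["qvalue"] < fdr])


# ----------------------------------------------------------------------
# design matrices
# ----------------------------------------------------------------------


def _design_matrices(t: AbundanceTable, design: str, contrast=None):
    """Full and reduced design matrices for the requested model.

    Returns (X_full, X_reduced, tested coefficient names, tested column
    indices in X_full).
    """
    meta = t.metadata.frame.loc[t.sample_ids]
    ones = np.ones((len(meta), 1))
    if design == "time":
        day = pd.to_numeric(t.metadata.require("day").loc[t.sample_ids])
        if day.isna().any():
            raise ValueError("time design requires a day value for every sample")
        X = np.column_stack([ones, day.to_numpy(dtype=float)])
        return X, ones, ["time"], [1]
    if design == "time2":
        tt = t.metadata.require("time2").loc[t.sample_ids].astype(int).to_numpy()
        X = np.column_stack([ones, tt])
        return X, ones, ["time2"], [1]
    if design == "phase":
        phase = t.metadata.require("phase").loc[t.sample_ids]
        levels = sorted(phase.unique())
        if len(levels) < 2:
            raise ValueError("phase design requires >= 2 observed levels")
        dummies = np.column_stack(
            [(phase == lv).to_numpy(dtype=float) for lv in levels[1:]]
        )
        X_full = np.column_stack([ones, dummies])
        names = [f"phase[{lv}]" for lv in levels[1:]]
        if contrast is None:  # joint test: all phase coefficients zero
            return X_full, ones, names, list(range(1, len(levels)))
        a, b = contrast
        if a not in levels or b not in levels:
            raise ValueError(f"contrast levels {contrast} not among {levels}")
        # 1-df contrast: reduced model merges levels a and b
        merged = phase.where(~phase.isin([a, b]), other=a)
        mlevels = sorted(merged.unique())
        mdum = np.column_stack(
            [(merged == lv).to_numpy(dtype=float) for lv in mlevels[1:]]
        ) if len(mlevels) > 1 else np.empty((len(meta), 0))
        X_red = np.column_stack([ones, mdum])
        return X_full, X_red, [f"phase[{b}]-phase[{a}]"], [(a, b, levels)]
    raise ValueError(f"unknown design {design!r}; expected time, time2 or phase")


def _check_full_rank(X: np.ndarray, what: str) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"{what} design matrix is not full rank")


# ----------------------------------------------------------------------
# NB GLM fitting
# ----------------------------------------------------------------------


def _fit_nb(y, X, offset, alpha):
    fam = sm.families.NegativeBinomial(alpha=max(alpha, _MIN_ALPHA))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=fam, offset=offset)
        return model.fit(maxiter=200, tol=1e-9)


def _profile_loglik(alpha, ys, X, offset) -> float:
    total = 0.0
    for y in ys:
        try:
            total += _fit_nb(y, X, offset, alpha).llf
        except Exception:
            return -np.inf
    return total


def _estimate_common_dispersion(ys, X, offset) -> float:
    """Profile-ML common dispersion under the full model (log-scale search)."""
    res = minimize_scalar(
        lambda la: -_profile_loglik(np.exp(la), ys, X, offset),
        bounds=(np.log(_MIN_ALPHA), np.log(_MAX_ALPHA)),
        method="bounded",
        options={"xatol": 1e-2},
    )
    return float(np.exp(res.x))


def _estimate_tagwise(ys, X, offset, common: float) -> np.ndarray:
    """Per-cluster profile ML, shrunk halfway toward the common value (log scale)."""
    out = np.empty(len(ys))
    for c, y in enumerate(ys):
        res = minimize_scalar(
            lambda la: -_profile_loglik(np.exp(la), [y], X, offset),
            bounds=(np.log(_MIN_ALPHA), np.log(_MAX_ALPHA)),
            method="bounded",
            options={"xatol": 1e-2},
        )
        out[c] = np.exp(0.5 * res.x + 0.5 * np.log(common))
    return out


def nb_test_designs(
    t: AbundanceTable,
    X_full: np.ndarray,
    X_reduced: np.ndarray,
    tested: list,
    kind: str = "lrt",
    dispersion: str = "common",
    design_name: str = "custom",
    offset: np.ndarray | None = None,
) -> DAResult:
    """Core NB test of a full vs nested reduced design, per cluster.

    ``tested`` names the tested coefficients; entries may be column names
    (int index into X_full) or ``(a, b, levels)`` tuples marking a pairwise
    phase contrast whose estimate is a coefficient difference.  ``offset``
    defaults to log(total clustered cells per sample).
    """
    kind = kind.lower()
    if kind not in ("lrt", "ql"):
        raise ValueError("kind must be 'lrt' or 'ql'")
    counts = t.counts.to_numpy(dtype=float)
    n_clusters, n_samples = counts.shape
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    _check_full_rank(X_full, "full")
    _check_full_rank(X_reduced, "reduced")
    df_test = X_full.shape[1] - X_reduced.shape[1]
    df_resid = n_samples - X_full.shape[1]
    if kind == "ql" and df_resid < 1:
        raise ValueError(
            f"quasi-likelihood test needs residual df >= 1 "
            f"(n_samples={n_samples}, p={X_full.shape[1]})"
        )
    if offset is None:
        totals = t.sample_totals()
        if (totals <= 0).any():
            raise ValueError("samples with zero clustered cells")
        offset = np.log(totals)
    else:
        offset = np.asarray(offset, dtype=float)
        if offset.shape != (n_samples,):
            raise ValueError("offset must have one entry per sample")
    nonzero = counts.sum(axis=1) > 0
    ys = [counts[c] for c in np.flatnonzero(nonzero)]
    if not ys:
        raise ValueError("all clusters have zero counts")
    common = _estimate_common_dispersion(ys, X_full, offset)
    if dispersion == "common":
        alphas_nz = np.full(len(ys), common)
    elif dispersion == "tagwise":
        alphas_nz = _estimate_tagwise(ys, X_full, offset, common)
    else:
        raise ValueError("dispersion must be 'common' or 'tagwise'")

    rows = []
    alpha_iter = iter(alphas_nz)
    for c in range(n_clusters):
        row = {
            "estimate": np.nan, "dispersion": np.nan, "stat": 0.0,
            "pvalue": 1.0, "flagged": False,
        }
        for name in _tested_names(tested):
            row[f"coef_{name}"] = np.nan
        if not nonzero[c]:
            row["flagged"] = True
            rows.append(row)
            continue
        alpha = float(next(alpha_iter))
        row["dispersion"] = alpha
        y = counts[c]
        try:
            full = _fit_nb(y, X_full, offset, alpha)
            red = _fit_nb(y, X_reduced, offset, alpha)
        except Exception:
            row["flagged"] = True
            rows.append(row)
            continue
        _fill_estimates(row, full, tested)
        if df_test == 0:
            rows.append(row)
            continue
        if kind == "lrt":
            stat = max(0.0, 2.0 * (full.llf - red.llf))
            p = float(scipy.stats.chi2.sf(stat, df_test))
        else:
            s2 = full.pearson_chi2 / df_resid
            s2_all = s2  # squeezed below, after the loop
            stat = max(0.0, (red.deviance - full.deviance))
            p = np.nan  # placeholder; finalised after squeezing
            row["_dev_drop"] = stat
            row["_s2"] = s2_all
            stat = stat / max(df_test, 1)
        row["stat"] = float(stat)
        row["pvalue"] = p
        rows.append(row)

    table = pd.DataFrame(rows, index=t.counts.index)
    if kind == "ql" and df_test > 0:
        fit_mask = table["_s2"].notna()
        mean_s2 = float(table.loc[fit_mask, "_s2"].mean())
        squeezed = 0.5 * table.loc[fit_mask, "_s2"] + 0.5 * mean_s2
        fstat = (table.loc[fit_mask, "_dev_drop"] / df_test) / squeezed
        table.loc[fit_mask, "stat"] = fstat
        table.loc[fit_mask, "pvalue"] = scipy.stats.f.sf(fstat, df_test, df_resid)
        table.loc[~fit_mask | table["flagged"], "pvalue"] = 1.0
        table = table.drop(columns=["_dev_drop", "_s2"])
    table["stat"] = table["stat"].fillna(0.0)
    table["pvalue"] = table["pvalue"].clip(0.0, 1.0).fillna(1.0)
    table["qvalue"] = multipletests(table["pvalue"].to_numpy(), method="fdr_bh")[1]
    return DAResult(table, "LRT" if kind == "lrt" else "QL", design_name)


def _tested_names(tested) -> list[str]:
    names = []
    for item in tested:
        if isinstance(item, tuple):
            a, b, _ = item
            names.append(f"phase[{b}]-phase[{a}]")
        else:
            names.append(str(item))
    return names


def _fill_estimates(row: dict, full_fit, tested) -> None:
    params = np.asarray(full_fit.params)
    single = []
    for item in tested:
        if isinstance(item, tuple):
            a, b, levels = item
            ref = levels[0]
            beta_a = 0.0 if a == ref else params[1 + levels[1:].index(a)]
            beta_b = 0.0 if b == ref else params[1 + levels[1:].index(b)]
            est = beta_b - beta_a
            row[f"coef_phase[{b}]-phase[{a}]"] = est
            single.append(est)
        elif isinstance(item, int):
            row[f"coef_{item}"] = params[item]
            single.append(params[item])
        else:
            row[f"coef_{item}"] = np.nan
    if len(single) == 1:
        row["estimate"] = float(single[0])


def _run_design(t, design, contrast, kind, dispersion):
    X_full, X_red, names, tested_cols = _design_matrices(t, design, contrast)
    tested: list = []
    for name, col in zip(names, tested_cols):
        if isinstance(col, tuple):
            tested.append(col)
        else:
            tested.append(col)
    # name tested integer columns by their design name
    res_name = {
        ("time", None): "time",
        ("time2", None): "time2",
    }.get((design, contrast))
    if res_name is None:
        res_name = (
            f"phase_pairwise({contrast[0]},{contrast[1]})"
            if contrast is not None
            else "phase_joint"
        )
    result = nb_test_designs(
        t, X_full, X_red, tested, kind=kind, dispersion=dispersion,
        design_name=res_name,
    )
    # rename integer coef columns to design names
    ren = {}
    for name, col in zip(names, tested_cols):
        if not isinstance(col, tuple):
            ren[f"coef_{col}"] = f"coef_{name}"
    result.table = result.table.rename(columns=ren)
    if len(names) == 1 and not isinstance(tested_cols[0], tuple):
        result.table["estimate"] = result.table[f"coef_{names[0]}"]
    return result


class NBAbundanceGLM(BaseEstimator):
    """Negative-binomial GLM differential-abundance estimator.

    Parameters
    ----------
    design : "time" | "time2" | "phase"
    test : "lrt" (chi-square likelihood ratio) | "ql" (quasi-likelihood F)
    dispersion : "common" | "tagwise"
    contrast : optional (levelA, levelB) pair for a 1-df phase contrast

    After ``fit(table)``: ``results_`` (:class:`DAResult`),
    ``dispersion_`` (per-cluster φ used), ``design_name_``.
    """

    def __init__(self, design: str = "time2", test: str = "lrt",
                 dispersion: str = "common", contrast=None):
        self.design = design
        self.test = test
        self.dispersion = dispersion
        self.contrast = contrast

    def fit(self, table: AbundanceTable, y=None) -> "NBAbundanceGLM":
        self.results_ = _run_design(
            table, self.design, self.contrast, self.test, self.dispersion
        )
        self.dispersion_ = self.results_.table["dispersion"].to_numpy()
        self.design_name_ = self.results_.design_name
        return self


def nb_glm_lrt(t: AbundanceTable, design: str = "time2", contrast=None,
               dispersion: str = "common") -> DAResult:
    """Likelihood-ratio chi-square NB test of the chosen predictor."""
    return NBAbundanceGLM(design, "lrt", dispersion, contrast).fit(t).results_


def nb_glm_ql(t: AbundanceTable, design: str = "time2", contrast=None,
              dispersion: str = "common") -> DAResult:
    """Quasi-likelihood F-test variant (conservative)."""
    return NBAbundanceGLM(design, "ql", dispersion, contrast).fit(t).results_


def phase_contrasts(t: AbundanceTable, kind: str = "lrt",
                    dispersion: str = "common") -> list[DAResult]:
    """One 1-df result per unordered pair of observed phase levels."""
    phase = t.metadata.require("phase").loc[t.sample_ids]
    levels = sorted(phase.unique())
    observed = [lv for lv in levels if (phase == lv).sum() >= 1]
    skipped = set(levels) - set(observed)
    if skipped:
        warnings.warn(f"phase levels without samples skipped: {sorted(skipped)}",
                      RuntimeWarning, stacklevel=2)
    out = []
    for a, b in combinations(observed, 2):
        out.append(_run_design(t, "phase", (a, b), kind, dispersion))
    return out
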