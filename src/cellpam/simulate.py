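"""Synthetic data with known cluster structure and abundance shifts.

Three generators, all fully reproducible from a seed:

* :func:`simulate_experiment` — a cell×gene count matrix with ``k_true``
  discrete cell types.  Each type elevates its own block of marker genes by
  ``exp(marker_log_fold)`` over a flat baseline; counts are negative
  binomial (variance μ + φμ²).  Cells are drawn per sample, and sample
  condition (the day ≤ 20 / > 20 split) shifts the cluster probabilities by
  ``condition_effect`` through a softmax.
* :func:`simulate_abundance` — a cluster×sample count table drawn
  multinomially from softmax-shifted proportions with log-normal
  sample-level proportion noise, for exercising the GLM layer directly.
* :func:`simulate_nb_table` — cluster×sample counts drawn exactly from the
  NB regression model (known intercept and log-fold-change per cluster),
  for coefficient-recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .abundance import AbundanceTable
from .matrix import ExpressionMatrix, SampleMetadata

__all__ = ["SimConfig", "simulate_experiment", "simulate_abundance",
           "simulate_nb_table"]


@dataclass
class SimConfig:
    """Parameters of the expression-level generator.

    ``condition_effect`` is a per-cluster log-fold shift of cluster
    probabilities in the day > 20 condition (None = no shift); sample sizes
    are log-normal around ``n_cells / n_samples`` to mimic uneven libraries.
    """

    n_cells: int = 2000
    n_genes: int = 400
    k_true: int = 3
    n_markers_per_cluster: int = 40
    marker_log_fold: float = 2.0
    base_mean: float = 0.3
    nb_dispersion: float = 0.4
    n_samples_per_condition: int = 8
    condition_effect: np.ndarray | None = None
    library_sigma: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cells", "n_genes", "k_true", "n_markers_per_cluster",
                     "n_samples_per_condition"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.base_mean <= 0 or self.nb_dispersion < 0:
            raise ValueError("base_mean must be > 0 and nb_dispersion >= 0")
        if self.k_true * self.n_markers_per_cluster > self.n_genes:
            raise ValueError(
                f"infeasible config: {self.k_true} clusters × "
                f"{self.n_markers_per_cluster} markers exceed {self.n_genes} genes"
            )
        if self.condition_effect is not None:
            self.condition_effect = np.asarray(self.condition_effect, dtype=float)
            if self.condition_effect.shape != (self.k_true,):
                raise ValueError("condition_effect must have one entry per cluster")


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = np.exp(logits - logits.max())
    return z / z.sum()


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    if phi <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / phi, scale=mean * phi)
    return rng.poisson(lam)


def simulate_experiment(cfg: SimConfig):
    """Draw (ExpressionMatrix, true_labels, SampleMetadata) from ``cfg``."""
    rng = np.random.default_rng(cfg.seed)
    k = cfg.k_true
    n_samples = 2 * cfg.n_samples_per_condition
    target = cfg.n_cells / n_samples
    sizes = np.maximum(
        10,
        np.round(
            rng.lognormal(np.log(target), cfg.library_sigma, size=n_samples)
        ).astype(int),
    )
    conditions = np.repeat([0, 1], cfg.n_samples_per_condition)
    sample_ids = [f"S{i + 1:02d}" for i in range(n_samples)]
    days = np.where(
        conditions == 0,
        rng.integers(12, 21, size=n_samples),
        rng.integers(21, 29, size=n_samples),
    )
    phase = np.where(days < 15, 3, np.where(days <= 20, 4, 5))
    base_logit = np.zeros(k)
    probs = {
        0: _softmax(base_logit),
        1: _softmax(
            base_logit
            + (cfg.condition_effect if cfg.condition_effect is not None else 0.0)
        ),
    }
    # cluster-specific gene means: flat baseline + a marker block per cluster
    means = np.full((k, cfg.n_genes), cfg.base_mean)
    for c in range(k):
        lo = c * cfg.n_markers_per_cluster
        means[c, lo : lo + cfg.n_markers_per_cluster] *= np.exp(cfg.marker_log_fold)

    labels, sample_of_cell, blocks = [], [], []
    for s in range(n_samples):
        cl = rng.choice(k, size=sizes[s], p=probs[conditions[s]])
        counts = _nb_draw(rng, means[cl], cfg.nb_dispersion)
        labels.append(cl)
        sample_of_cell.extend([sample_ids[s]] * sizes[s])
        blocks.append(sp.csr_matrix(counts))
    counts = sp.vstack(blocks).tocsr()
    labels = np.concatenate(labels)
    n_total = counts.shape[0]
    cells = [f"cell{i:06d}" for i in range(n_total)]
    genes = [f"gene{j:04d}" for j in range(cfg.n_genes)]
    meta = SampleMetadata(
        pd.DataFrame({"sample_id": sample_ids, "day": days, "phase": phase})
    )
    m = ExpressionMatrix(counts, cells, genes, np.array(sample_of_cell, dtype=object))
    return m, labels, meta


def _abundance_meta(n_per_condition: int, rng: np.random.Generator) -> SampleMetadata:
    n_samples = 2 * n_per_condition
    conditions = np.repeat([0, 1], n_per_condition)
    days = np.where(
        conditions == 0,
        rng.integers(12, 21, size=n_samples),
        rng.integers(21, 29, size=n_samples),
    )
    phase = np.where(days < 15, 3, np.where(days <= 20, 4, 5))
    return SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": [f"S{i + 1:02d}" for i in range(n_samples)],
                "day": days,
                "phase": phase,
            }
        )
    )


def simulate_abundance(
    n_clusters: int = 10,
    n_samples_per_condition: int = 8,
    cells_per_sample: int = 2000,
    condition_effect: np.ndarray | None = None,
    bio_sigma: float = 0.15,
    library_sigma: float = 0.25,
    seed: int = 0,
) -> AbundanceTable:
    """Cluster×sample counts with optional condition-dependent shifts.

    Per-sample cluster proportions are softmax(base + effect·condition +
    noise) with i.i.d. Normal(0, ``bio_sigma``) log-proportion noise (the
    biological sample-to-sample variability the NB dispersion absorbs);
    cell totals are log-normal around ``cells_per_sample``.
    """
    rng = np.random.default_rng(seed)
    meta = _abundance_meta(n_samples_per_condition, rng)
    condition = meta.frame["time2"].to_numpy()
    if condition_effect is None:
        condition_effect = np.zeros(n_clusters)
    condition_effect = np.asarray(condition_effect, dtype=float)
    if condition_effect.shape != (n_clusters,):
        raise ValueError("condition_effect must have one entry per cluster")
    counts = np.zeros((n_clusters, len(meta)), dtype=np.int64)
    for s in range(len(meta)):
        logits = (
            condition[s] * condition_effect
            + rng.normal(0.0, bio_sigma, size=n_clusters)
        )
        p = _softmax(logits)
        total = max(
            n_clusters,
            int(round(rng.lognormal(np.log(cells_per_sample), library_sigma))),
        )
        counts[:, s] = rng.multinomial(total, p)
    frame = pd.DataFrame(
        counts,
        index=[f"c{c}" for c in range(n_clusters)],
        columns=meta.sample_ids,
    )
    return AbundanceTable(frame, meta)


def simulate_nb_table(
    beta: np.ndarray,
    n_samples_per_condition: int = 8,
    cells_per_sample: int = 2000,
    base_share: float = 0.05,
    dispersion: float = 0.1,
    seed: int = 0,
):
    """Counts drawn exactly from the NB regression model.

    Cluster c in sample s has mean ``base_share · exp(beta[c]·x_s) · T`` with
    x_s the binary condition and T = ``cells_per_sample``; returns
    ``(AbundanceTable, offsets)`` where ``offsets`` is the true log(T) vector
    to use as the model offset.
    """
    beta = np.asarray(beta, dtype=float)
    rng = np.random.default_rng(seed)
    meta = _abundance_meta(n_samples_per_condition, rng)
    x = meta.frame["time2"].to_numpy()
    mean = base_share * np.exp(np.outer(beta, x)) * cells_per_sample
    counts = _nb_draw(rng, mean, dispersion)
    frame = pd.DataFrame(
        counts,
        index=[f"c{c}" for c in range(len(beta))],
        columns=meta.sample_ids,
    )
    offsets = np.full(len(meta), np.log(cells_per_sample))
    return AbundanceTable(frame, meta), offsets
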