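# cellpam

Memory-efficient PAM (k-medoids) clustering and negative-binomial
differential cell-abundance testing for single-cell RNA-seq.

## What it is for

Differential-abundance analysis asks whether the composition of a tissue —
the share of each cell population — changes with a phenotype, for example
across the days of the menstrual cycle in endometrial biopsies.  The
workflow has three stages:

1. **cluster** all cells, ignoring phenotype, to define populations;
2. **count** cells per cluster and per biological sample;
3. **model** those counts against the samples' phenotypic covariates.

For stage 1 this package implements *Partitioning Around Medoids* (PAM),
whose cluster centres are real cells (medoids) rather than synthetic
centroids, at the scale single-cell data demands: pairwise dissimilarities
are held in packed strict-lower-triangular storage with selectable 4- or
8-byte precision (half the memory in single precision), computed by
sparse-aware kernels that skip components zero in both cells, and
parallelised so that every worker handles the same number of pairs and the
result is bit-identical for any worker count.

PAM minimises

```
TD = Σᵢ d(xᵢ, m(xᵢ)),   m(xᵢ) = the medoid nearest to cell xᵢ,
```

with greedy **BUILD** initialisation and the deterministic **FASTPAM1**
swap phase, which evaluates every (candidate, medoid) exchange in O(n) per
candidate using cached nearest/second-nearest medoid distances and applies
the best strict improvement until none remains (PAM-BS).  Dissimilarities:
Manhattan (L1), Euclidean (L2) and the Pearson dissimilarity 1 − |r|.

Around the clusterer: per-cell QC filtering, the `rawn` and `log1n`
normalisations, vst-style highly-variable-gene selection, silhouette widths
`s(i) = (b−a)/max(a,b)` with an iterative low-silhouette cell filter, the
Adjusted Rand Index for partition comparison, and for stage 3 a
negative-binomial GLM with log link and offset log(cells per sample),
tested by likelihood-ratio chi-square or a conservative quasi-likelihood F
over `time` (cycle day), `time2` (day ≤ 20 vs > 20) and `phase` designs,
with Benjamini–Hochberg correction across clusters.  A seeded synthetic
generator produces count matrices with known cluster structure and
abundance shifts, so the whole stack is testable offline.

## Worked example

```python
import numpy as np
from cellpam import (SimConfig, simulate_experiment, normalize_log1n,
                     compute_dissimilarity, pam, silhouette,
                     adjusted_rand_index, cluster_sample_counts, nb_glm_lrt)

cfg = SimConfig(n_cells=2000, n_genes=400, k_true=3, marker_log_fold=3.0,
                condition_effect=np.array([np.log(3), 0.0, 0.0]), seed=1)
m, truth, meta = simulate_experiment(cfg)          # 2,088 cells × 400 genes
D = compute_dissimilarity(normalize_log1n(m), metric="Pearson",
                          precision="single", workers=2)
res = pam(D, 3)                                    # PAM-BS, deterministic
print(adjusted_rand_index(truth, res.labels))      # 1.0
print(silhouette(D, res.labels).global_mean)       # 0.539
table = cluster_sample_counts(res.labels, m.sample_of_cell, meta)
da = nb_glm_lrt(table, design="time2")
print(da.table[["estimate", "stat", "qvalue"]].round(4))
```

prints

```
1.0
0.5394...
         estimate     stat  qvalue
cluster
0          0.6277  93.0524     0.0
1         -0.4902  33.0444     0.0
2         -0.6407  51.6076     0.0
```

The simulation tripled cluster 0's abundance after cycle day 20; clustering
recovers the three cell types exactly (ARI 1.0), and the GLM estimates a
log-fold change of 0.63 for cluster 0's *share* of each sample —
log(0.25/0.125) ≈ 0.69 is the truth on the share scale, smaller than log 3
because shares are compositional: when one cluster grows the others'
shares must shrink, which is why clusters 1 and 2 show compensating
negative estimates and are also flagged.

A scikit-learn-style estimator interface is available for the fit-shaped
pieces (`PAM`, `SilhouetteFilter`, `NBAbundanceGLM`), e.g.
`PAM(n_clusters=3, metric="Pearson").fit(X)` with `labels_`,
`medoid_indices_`, `inertia_` and `get_params`/`set_params`.

## Command line

Every stage is a subcommand of `cellpam`:
`qc`, `normalize`, `hvg`, `dist`, `pam`, `silhouette`, `filter`, `counts`,
`da`, `ari`, `simulate`, and `run` (the whole chain from a flat key:value
YAML config, with a manifest for reproducibility):

```sh
cellpam simulate --seed 1 --out simdir
cellpam dist --mtx simdir/sim.mtx --barcodes simdir/sim_barcodes.tsv \
             --features simdir/sim_features.tsv \
             --metric Pearson --precision single --workers 4 --out d.bin
cellpam pam --dissim d.bin --k 3 --labels-out labels.tsv --medoids-out medoids.tsv
cellpam ari --truth simdir/truth_labels.tsv --pred labels.tsv
```

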