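# Methods

This note documents the models and algorithms implemented in `cellpam`, the
numerical choices behind them, what the synthetic generator does and does
not emulate, and known limitations.

## Dissimilarities and packed storage

For n cells the pairwise dissimilarity matrix is stored as the strict lower
triangle in row-major packed order: pair (i, j), i > j, lives at index
i(i−1)/2 + j, so the payload is exactly n(n−1)/2 entries.  Storage precision
is selectable (float32 or float64); at 60,000 cells the packed single-
precision payload is 6.71 GiB, half of double.  Arithmetic is always carried
out in double precision — storage, not accumulation, is the memory
bottleneck at scale — and values are cast once on store.

Three dissimilarities are implemented as compiled kernels that walk the CSR
structure of the expression matrix:

* **L1** (Manhattan) and **L2** (Euclidean): merged traversal of the two
  rows' sorted support; components zero in both cells are never touched,
  components zero in exactly one cell reduce to a one-sided term.
* **Pearson**, d = 1 − |r| ∈ [0, 1]: r is computed from a dot product over
  the common support plus per-row means and population standard deviations
  precomputed once; zero–zero components enter the centred statistic
  analytically.  A constant row has no defined correlation; by convention
  d = 1 against any other row and d = 0 against an identical constant row,
  with a warning.  r is clamped to [−1, 1] before taking |·|.

Parallel execution splits the packed index range into `workers` contiguous
chunks of equal size (±1 pair), so all threads do the same amount of work
and the output is bit-identical for any worker count.  Because IEEE
addition of an exact 0.0 term is the identity, the sparse kernels also
agree bit-for-bit with a dense reference kernel that visits every component
in the same index order; the test suite asserts both properties.

## PAM: BUILD + FASTPAM1 (PAM-BS)

The objective is TD = Σᵢ d(xᵢ, nearest medoid).

**BUILD** picks the first medoid as the point minimising total distance to
all others, then greedily adds the point giving the largest TD reduction
against the running nearest-medoid distances.  **FASTPAM1** then evaluates,
at each iteration, the TD change of every (non-medoid candidate c, medoid
position i) exchange in one O(n) pass per candidate: with dₙ and dₛ the
cached distances of each point to its nearest and second-nearest medoid,
the change decomposes into a shared term Σₒ min(0, d(o,c) − dₙ(o)) plus a
per-medoid correction min(d(o,c), dₛ(o)) − dₙ(o) − min(0, d(o,c) − dₙ(o))
accumulated on the column of o's nearest medoid.  The single best swap is
applied and the caches rebuilt; the loop stops when no swap strictly
reduces TD.

Numerical/tie conventions, all chosen to make the procedure fully
deterministic (no convergence tolerance is stated by the algorithm family,
and determinism needs explicit rules):

* improvement means ΔTD < 0 strictly, in double precision;
* every argmin tie (initial medoid, BUILD candidate, best swap, nearest
  medoid) goes to the lowest index — for swaps, lowest candidate index,
  then lowest medoid position;
* TD after each swap is recomputed from the caches rather than accumulated,
  so the reported trace is exact and strictly decreasing;
* `max_iter` (default 1000) caps the swap phase as a guard; observed runs
  converge in a handful of iterations and the result carries a
  `converged` flag.

**LAB** is provided as a faster seeded initialisation: each of the k
medoids is chosen by a BUILD step restricted to a fresh random subsample of
10 + ⌈√n⌉ points.  With BUILD the whole pipeline is deterministic; the seed
is consumed only by LAB.

PAM never materialises the full n×n matrix: all passes expand packed rows
in fixed 256-row chunks, keeping peak memory at O(n·chunk) above the packed
payload.

## Silhouettes and the cell filter

s(i) = (b−a)/max(a,b) with a(i) the mean dissimilarity to the other members
of i's cluster and b(i) the smallest mean dissimilarity to another cluster;
s(i) = 0 for singletons, and when a = b = 0 (a point equidistant and at
zero distance to two clusters) s is defined as 0.  Computation is chunked
and worker-invariant like the kernels above.

The filter iterates: compute silhouettes; stop when at least a target
fraction (default 60%) of current cells have s strictly above the threshold
(default 0.7); otherwise remove the ⌊drop_frac·n⌋ lowest-s cells (at least
one, ties resolved toward the lower cell index; default drop 15%).
Survivor dissimilarities are extracted from the packed matrix, never
recomputed, so no drift accumulates.  Whether the clustering should be
refreshed between rounds is genuinely open; the package re-runs PAM on the
survivors with the same k when `recluster_k` is set, because downstream
per-cluster counts should refer to medoids of the cells that remain.  Each
round strictly reduces the cell count, so termination is guaranteed; if the
criterion is never met the last non-empty state is returned flagged unmet.

## Differential abundance

Counts y₍c,s₎ of cluster c in sample s are modelled per cluster as negative
binomial (variance μ + φμ²) with log link and offset log(total clustered
cells in sample s), so coefficients are log-fold changes of a cluster's
*share* of a sample — cluster counts are compositional within a sample, and
no further between-sample normalisation is applied.  Shares are
interlinked: a genuine expansion of one population necessarily depresses
the others' shares, which readers of the estimates should keep in mind.

Designs: `time` (numeric day), `time2` (binary day ≤ 20 / > 20, the split
bracketing the window of implantation), and `phase` (treatment-coded
categorical, lowest level as reference) tested jointly or as 1-df pairwise
contrasts; a pairwise contrast is fit as the LRT against the reduced model
in which the two levels are merged, and its estimate is the corresponding
coefficient difference.

The dispersion φ is estimated by profile maximum likelihood under the full
model — a bounded scalar search on log φ over [10⁻⁶, 10²] (absolute
tolerance 10⁻² on the log scale, ample since the likelihood is flat at that
resolution) — either common across clusters (default) or per-cluster shrunk
halfway toward the common value on the log scale ("tagwise").  This is a
transparent, testable estimator of the same quantity that empirical-Bayes
machinery targets; it does not reproduce any external package's shrinkage
exactly.  GLM fits use statsmodels' IRLS.

Tests per cluster: **LRT** 2(ℓ_full − ℓ_reduced) against χ² with df = number
of tested coefficients; **QL**, a deliberately conservative variant, scales
the deviance drop by a squeezed quasi-dispersion (the cluster's Pearson
χ²/df averaged half-and-half with the across-cluster mean) and refers to an
F distribution with (df_test, residual df).  All-zero clusters are flagged
and reported with p = 1; p-values are BH-adjusted across clusters, and
"significant" means q < 0.05.

## Synthetic data

`simulate_experiment` draws discrete cell types: per sample (log-normal
cell totals, σ = 0.25, mimicking uneven libraries), cluster memberships are
categorical with probabilities softmax-shifted by a per-cluster condition
effect in the day > 20 condition; gene counts are NB (default φ = 0.4)
around a flat base mean (default 0.3) with a disjoint marker block per
cluster elevated by exp(marker_log_fold).  Defaults (2,000 cells, 400
genes, 3 types, 40 markers, log-fold 2, 8 samples per condition) give a
sparse (~70% zeros) matrix whose types are separable but not trivial;
recovery checks use log-fold 3, the well-separated regime.

`simulate_abundance` skips the expression layer and draws the cluster×sample
table directly: per-sample cluster proportions are
softmax(effect·condition + ε) with ε ~ N(0, 0.15) log-proportion noise (the
biological sample-to-sample variability the NB dispersion absorbs), totals
log-normal around 2,000 cells, counts multinomial.  `simulate_nb_table`
draws counts exactly from the NB regression model with known coefficients
for recovery checks.

What the generators do **not** emulate: ambient RNA, doublets, batch
effects, gene–gene correlation beyond the marker blocks, library-specific
capture efficiencies, or continuous (trajectory-like) states.  Passing
tests therefore demonstrate algorithmic correctness and statistical
calibration under the stated model, not robustness to those artifacts.

## Problem sizes in the checks

The statistical acceptance checks run at the sizes the analysis design
states: 10 clusters, 8 + 8 samples, ~2,000 cells per sample, with 200
null replicates for type-I calibration and 100 replicates for power;
algorithmic oracle checks use exhaustive enumeration at n ≤ 12 (swap
bookkeeping, local optimality) and n ≤ 50 (greedy initialisation), and
end-to-end recovery uses 600 cells × 200 genes — sizes at which exhaustive
references remain exact.

## Known limitations

* The QL variant is a documented stand-in for empirical-Bayes
  quasi-likelihood pipelines, sharing their direction (conservative) but
  not their exact squeezing.
* The vst HVG trend uses a local-linear lowess (span 0.3) on log₁₀ variance
  vs log₁₀ mean with standardised values clipped at √n; implementations
  differing in the trend fit can rank borderline genes differently, so a
  user-supplied HVG list is the contract-safe path.
* `log1n` is read as "divide each cell's log(1+count) values by their
  per-cell total"; the alternative reading (log of the rawn values) would
  differ and both are defensible.
* Pearson dissimilarity is not a metric (no triangle inequality); L1/L2
  are.
* LAB quality depends on the subsample size; BUILD is the default for a
  reason.
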