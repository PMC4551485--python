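# Methods

## Model and procedure

`coexgraph` tests, per predefined gene set, whether the co-expression
structure among the set's genes differs between two phenotypes.

1. **Graph construction.** Within each phenotype's samples, every gene pair
   gets a dependence test (Pearson, Spearman, or Kendall). A pairwise
   *association degree* in [0, 1] is derived on one of three scales:
   |correlation|, 1 − p, or 1 − BH(p), where BH is the Benjamini–Hochberg
   adjustment over the set's n(n−1)/2 pair p-values. The graph is either
   fully weighted by these degrees or thresholded to an unweighted graph.
   The default — used in every simulation here — is the weighted graph with
   Spearman 1 − BH(p) edges.
2. **Spectral fingerprint.** The adjacency spectrum (eigenvalues of the
   symmetric weight matrix, which sum to zero because the diagonal is zero)
   is rescaled by 1/n_V and smoothed into a density by a Gaussian kernel
   estimate. The spectral entropy −∫ρ log ρ dλ (natural log, 0·log 0 = 0)
   measures structural randomness; the Jensen–Shannon divergence between
   two spectral densities measures structural difference, is bounded by
   log 2, and its square root is a metric.
3. **Permutation test.** Θ ≥ 0 is one of seven graph distances (spectral JS
   by default). Sample-phenotype labels are shuffled B times preserving
   group sizes and Θ recomputed; p = (1 + #{Θ_b ≥ Θ_obs}) / (1 + B). The
   "+1" keeps the test valid (p can never be 0, and under H₀ the p-value is
   stochastically no smaller than uniform). Across gene sets, q-values come
   from the same BH step-up.

## Statistical assumptions

- Samples are exchangeable under H₀ within the pooled group, which is what
  makes the label-permutation null exact. Confounders that differ between
  phenotypes (batch, composition) violate this and are not modelled.
- Dependence-test p-values use large-sample approximations: a t
  distribution on the coefficient with n − 2 df for Pearson and Spearman
  (average ranks for ties), the normal approximation for Kendall tau-b.
  These are accurate for group sizes of about 20 and up, which is also the
  practical minimum for estimating co-expression at all. Because the same
  approximation is applied to observed and permuted data, approximation
  error largely cancels in the permutation p-value.
- Constant genes (possible in permuted subsets or degenerate data) degrade
  to zero association with a warning instead of erroring, so permutation
  replicates never abort.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `method` | spearman | pairwise dependence test |
| `scale` | one_minus_fdr | association degree: 1 − BH-adjusted p |
| `mode` / `threshold` | weighted / – | thresholding only for unweighted graphs |
| `B` | 1000 (simulation), 10000 (data analysis) | label permutations per set |
| `min_size` | 20 | minimum post-intersection set size |
| bandwidth criterion | sturges | kernel bandwidth rule for densities |
| grid points | 512 | density evaluation grid |

Sets smaller than ~20 genes give unstable network estimates; sets much
larger than ~1000 genes are computationally heavy (the eigendecomposition
is O(n³) per permutation).

## Numerical choices

- **Bandwidths.** Sturges' criterion is read as the bin width of a Sturges
  histogram, h = range / ⌈log₂ n + 1⌉; Silverman's rule is
  0.9·min(sd, IQR/1.34)·n^(−1/5) with the n − 1 variance divisor. A
  degenerate zero bandwidth (all values equal) falls back to
  10⁻³·max(1, |max|) so point-mass spectra still yield a density.
- **Shared-grid protocol.** JS requires both densities on one measure: the
  512-point grid spans the pooled eigenvalue range padded by three times
  the larger of the two per-graph bandwidths. Each density keeps its own
  bandwidth and is renormalized to trapezoid integral 1 on that grid.
- **Eigenvalue rescaling.** Eigenvalues are divided by n_V before density
  estimation. Compared graphs always share n_V within a test, so this
  cannot change JS-based p-values; it shifts each entropy by the additive
  constant log n_V, which cancels in entropy differences (asserted
  numerically in the tests).
- **Logs and zeros.** Natural logs everywhere; densities are floored at
  10⁻¹² inside logarithms while true zeros contribute 0 (the 0·log 0
  convention). KL is +∞ when the reference density vanishes where the
  first density exceeds the floor; JS is always finite.
- **Centrality distances.** "Adjusted for the gene set size" is implemented
  as the Euclidean norm divided by n_V — a per-gene discrepancy. Any
  monotone rescaling of Θ leaves permutation p-values unchanged for fixed
  n_V (asserted in the tests), so the divisor choice is inconsequential for
  inference.
- **Weighted path lengths and clustering.** Edge length is 1/w (strong
  association = short path), averaging over reachable ordered pairs only so
  sparse permuted graphs stay finite; weighted clustering is Onnela's
  geometric-mean coefficient with max-weight normalization; betweenness and
  closeness are restricted to unweighted graphs.
- **Probe collapsing.** One row per gene symbol, represented by the probe
  with the highest mean expression (ties to the lexicographically smallest
  probe id) — the common gene-set-analysis default.
- **Per-set seeds** derive from (master seed, CRC32 of the set name), so
  adding or removing sets from a collection never perturbs another set's
  p-value, and replicate seeds in the Monte Carlo experiments derive from
  (master seed, replicate index), so results are independent of execution
  order.

## Synthetic data generator

`SimulationConfig`/`generate_expression` draw genes × samples matrices from
a zero-mean multivariate normal with block-constant correlation via the
Cholesky factor: genes within a block share pairwise correlation ρ, blocks
are mutually independent, and `noise_sd` scales all marginal standard
deviations. The default pool — 50 genes in 5 blocks of 10 at ρ = 0.6, 200
samples — emulates a panel of tightly co-expressed gene modules, the
structure the power experiment needs to have signal to destroy.

What it does **not** emulate: heavy-tailed or skewed expression marginals,
platform/batch effects, hub-dominated (scale-free) correlation topology,
inter-module correlation, or mean-level differential expression. Passing
the calibration and power checks here therefore demonstrates properties of
the *test* (validity under exchangeable resampling; sensitivity to
destroyed correlation structure), not performance guarantees on any
particular real dataset.

## Monte Carlo experiments

- **Type-I error.** Two groups (default 65 and 30 columns) are resampled
  with replacement from the one pool per replicate — so H₀ holds by
  construction — a random gene set is drawn, and the spectral JS
  permutation test runs. The fraction of p ≤ α estimates the false-positive
  rate; validity requires it to track α, checked within three binomial
  standard errors at α ∈ {0.01, 0.05, 0.10}.
- **Power.** Per replicate, 2 × 40 columns are drawn, split in half, and
  ⌈γ · 50⌉ of a 50-gene set's genes have their values independently
  permuted across the second group's samples, destroying that group's
  correlation structure while leaving marginals intact. Rejection rates
  over the α grid {0.005, …, 1} are summarised by the trapezoidal ROC area
  (anchored at (0, 0)): 0.5 at γ = 0, approaching 1 as γ grows.
- **Problem sizes.** The packaged experiments run 200 replicates × 200
  permutations, a desk-scale setting with binomial tolerances widened
  accordingly; both counts are CLI flags (`--reps`, `--perms`) for
  full-scale runs at 1000 × 1000.

## Known limitations

- The FDR scope for edge p-values is per gene set (the only scope
  computable when sets are analyzed independently under permutation);
  genome-wide edge FDR would give systematically different edge weights.
- JS divergences between kernel density estimates are biased away from zero
  for finite spectra (two independent draws from one model never give
  exactly coincident densities); the permutation null absorbs this bias,
  which is why inference is calibrated even though raw Θ values are not
  comparable across set sizes.
- Exact-permutation dependence-test p-values, partial correlations, and
  mutual-information edges are out of scope, as are Laplacian spectra.
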