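# Methods

## Problem and model

House-dust metagenomes expose occupants to hundreds of microbial taxa
simultaneously, and taxon abundances are mutually dependent (compositional,
correlated). Testing taxa one at a time against a continuous respiratory
outcome conflates each taxon's association with that of its correlates.
dustdab instead fits all taxa jointly:

y = Xβ + Zγ + ε,  ε ~ N(0, σ²I)

where y is the outcome (standardized), X the n × p matrix of centered and
scaled taxon relative abundances, and Z the covariate block. With p of the
same order as n, ordinary least squares is unstable or undefined, so β is
estimated by the Lasso and each coordinate is subsequently *desparsified*
so that it admits an asymptotically normal test of H₀: β_j = 0 that
controls for all other taxa. The key assumptions are: sparsity of the true
signal (s ≪ n/log p), sub-Gaussian noise, and a well-conditioned population
covariance of the predictors; the operating-characteristic studies below
probe how far the method holds up at the data's actual n, p and design.

### Covariates

Covariates are never penalized: shrinking a confounder's coefficient would
re-introduce confounding. Equivalently (Frisch–Waugh), X and y are
residualized on [1, Z] and the penalized problem is solved on the
residualized design; the unpenalized part is recovered exactly. Rosters per
outcome: FEV₁ and FEV₁/FVC use age, age², sex, height, height², smoking
(former/current vs never), pack-years, asthma, state (NC vs IA reference),
and ancestry (non-European vs European reference); FVC adds weight; FeNO
drops the quadratic terms. A winter-season indicator can be appended as a
sensitivity adjustment. Complete-case analysis per outcome, with dropped
rows logged.

### Penalty selection

λ is chosen on a 100-point log grid spanning three decades below
λ_max = max_j |x_jᵀỹ|/n by 5-fold cross-validation (seeded shuffled
partition), minimizing mean held-out squared error; the covariate
projection is refit inside each training fold so no information leaks from
held-out samples. The minimizing λ is used (not the 1-SE rule).

### Desparsification

Θ̂ is assembled from nodewise Lasso regressions of each column on the rest;
τ_j² = x_jᵀ(x_j − X₋ⱼγ̂_j)/n scales row j. Nodewise penalties are chosen
per column by 5-fold CV on a 10-point grid spanning 1.5 decades below that
column's λ_max — penalties far below √(log p / n) only slow coordinate
descent without materially changing Θ̂. With λ_node = 0 (full-rank X),
Θ̂ is the exact inverse of Σ̂ and the whole construction collapses to OLS
with classical standard errors; the test suite asserts this identity to
1e-6 and better.

The noise level σ̂ is the residual SD of the penalized fit with a
degrees-of-freedom correction df = n − ŝ − q (ŝ = selected support,
q = unpenalized parameters). A scaled-lasso variance estimator would be a
reasonable alternative; it is not implemented, and under the null-heavy
regimes studied here the df-corrected estimator is already approximately
unbiased (empirical type-I error 0.049 at nominal 0.05).

P-values are reported without multiplicity correction at the fixed 0.05
convention — the joint model already adjusts each test for all other taxa —
and a Benjamini–Hochberg q-value column is emitted for reference without
ever changing the significance flag.

## Preprocessing chain and its order

filter → aggregate to rank → winsorize → relative abundance → standardize.

- Sample filter (< 1000 reads, strict) precedes the taxon filter
  (< 0.0005% of the retained grand total, strict; taxa exactly at the
  threshold are kept), evaluated once, not iterated.
- Winsorization caps each taxon's five largest counts at the sixth largest
  (idempotent; ties make it a no-op). Relative abundances divide by the
  *winsorized* sample totals so the composition stays internally
  consistent.
- Relative abundance is per-sample-total (the standard compositional
  reading).
- Standardization uses the sample SD (ddof = 1) for both X and y; the
  choice only rescales all coefficients by √(n/(n−1)) relative to the
  population-SD convention. Constant columns are dropped with a warning and
  surface in results with NA statistics.

## Alpha diversity

Diversity is computed on counts rarefied once (multivariate hypergeometric,
i.e. subsampling without replacement) to the minimum retained sample depth,
with the rarefaction seed recorded; richness is the count of nonzero taxa
and H = −Σ p_i ln p_i in nats. H is exponentially transformed to the
effective species number e^H before the OLS association — the natural-log
base and plain e^H convention follow the standard vegan usage. Differential
abundance uses unrarefied counts; diversity and abundance are two separate
branches from the filtered table.

## Synthetic data generator

The generator emulates a post-classification, post-decontamination dust
count table at genus level:

- **Depths**: log-normal reads per sample, defaults μ = 11.2, σ = 1.43 —
  solved so that ~780 samples have mean depth ≈ 2.2 × 10⁵ and minimum near
  10³.
- **Composition**: per-sample Dirichlet draw with a harmonic-decay
  concentration vector a_j ∝ 1/j scaled to total concentration 300, then a
  multinomial read draw. The decay fixes dominance (top 3 taxa ≈ 28% of
  reads); the total concentration sets between-sample variability and hence
  the zero-cell fraction (~0.27 at default scale, inside the targeted
  0.15–0.40 band). Per-taxon dispersion is a tuning choice, not an
  observed quantity.
- **Covariates**: cohort-like marginals (age 62 ± 11, 60% male,
  never/former/current smoking 65/29/6%, asthma 38%, NC 32%, non-European
  4%, winter 23%; pack-years positive only in ever-smokers).
- **Outcomes**: η = Z_std γ + X_std β + N(0, noise_sd²) on the analysis
  scale, with X_std the standardized relative-abundance matrix after the
  same preprocessing the inference applies — so the planted β lives on the
  scale the estimator targets, making parameter recovery well-posed. η is
  mapped affinely to storage units (ml for spirometry; FeNO stored as
  exp(ln-scale), recovered affinely by the ln transform; FEV₁/FVC clipped
  to (0, 1], a negligible tail nonlinearity at the default scale 0.05).
  Covariate effects apply to internally z-scored covariates (default 0.2
  per column) to avoid unit-dependent slopes. Causal taxa are drawn from
  the more abundant half of taxa so rare-taxon filtering cannot silently
  delete planted signal.

What the generator does **not** emulate: taxonomic misclassification,
batch/plate effects, reagent contamination, absolute-load differences, and
spatial or seasonal structure beyond a bare winter flag. Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated generative model, not robustness to those real-data artifacts.

## Operating-characteristic studies

Type-I error, p-value calibration, coverage and power are measured with the
design matrix held fixed and outcomes redrawn per replicate —
conditional-on-design frequentist evaluation, the setting in which
desparsified-Lasso guarantees are stated. This also allows Θ̂ (a function
of X alone) to be computed once per study. Problem sizes: n = 400, p = 100,
500 replicates for null and coverage studies, 200 for power; each replicate
re-runs its own 5-fold CV. KS uniformity is assessed per coordinate across
replicates (those p-values are iid under the null), not pooled across
coordinates within a replicate (which are dependent through the shared
outcome draw).

Measured at these sizes: type-I error 0.049, 95% CI coverage 0.951
(non-null coordinates 0.951), sign-consistent power 1.0 for standardized
effects of 0.3, and end-to-end recovery of all planted genera through the
full count-table pipeline with false positives at ≈ 0.04.

## Numerical choices and degenerate inputs

- Coordinate descent (scikit-learn) with tol 1e-10 for the main fit; every
  returned fit satisfies the KKT conditions within 1e-6. λ = 0 is solved by
  least squares directly.
- Nodewise residual variance below 1e-12 raises a collinearity error naming
  the offending taxon; non-positive residual df raises with advice to
  increase n or the penalty.
- Zero-total samples, all-filtered tables, mismatched sample universes,
  negative or fractional counts, unknown categorical levels, and FEV₁/FVC
  outside (0, 1] are all hard errors, never silent fixes.
- Run manifests record input hashes, seeds, thresholds and stage dimensions
  and contain no wall-clock data, so identical runs serialize identically.

## Known limitations

- Relative abundances carry the compositional sum constraint; one column is
  near-redundant given the rest, which the nodewise penalty absorbs, but
  coefficients must be read as effects of a taxon's share, not its absolute
  load.
- The desparsified construction is one canonical choice among
  post-selection inference variants; finite-sample corrections beyond the
  df-adjusted σ̂ are not applied.
- One λ per outcome (no per-fold refitting of the final model); the 1-SE
  rule is not offered.
- Species-level analysis is supported mechanically but inherits the
  sparsity problems genus aggregation exists to avoid.
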