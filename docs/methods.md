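# Methods

This note documents the models, their assumptions, the synthetic-data
generator, numerical choices, and known limitations. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Statistical models

### Field-trial BLUEs

Each environment × element trial is fitted with

    y = μ + X l + Z_row u_row + Z_col u_col + Z_rep u_rep + e,

line effects `l` fixed (cell-means coding, so the GLS coefficient *is* the
BLUE of μ + l), and row, column and replicate as independent
identity-covariance random effects. The model is parameterised by variance
ratios γ_f = σ²_f/σ²_e; the residual variance is profiled out of the REML
likelihood and the ratios are optimised by Nelder–Mead on the log scale
(two starts, max 500 iterations, fatol 1e-8). Variance components are
non-negative by construction (exp transform); random terms with fewer than
two levels are dropped and reported. When every line has a single plot the
design is saturated: BLUEs equal plot values, all variance components are
reported 0, and standard errors are undefined (NaN).

This is a deliberate simplification of the spatial adjustments used with
commercial mixed-model software: only the named row/column/replicate terms
are modelled, no AR1×AR1 residual correlation. The generator makes the
matching simplification (below), so the pipeline is internally consistent;
on real data with strong autocorrelated spatial trends the BLUEs will be
less efficient than a full spatial model.

### GRM

Standardised-dosage relatedness with allele frequencies estimated from the
analysed lines. For fully inbred material the diagonal is ≈ 2 (1 + F with
F = 1); this is expected and harmless — the mixed models estimate variance
scales from the data. `stabilize` shifts the diagonal just enough to make
the smallest eigenvalue non-negative (spectral shift, default ε = 1e-6) so
Cholesky/eigen factorisations downstream are well posed. For subset
environments the GWAS uses the sub-matrix of the full-panel GRM without
re-estimating frequencies, keeping t-value signs comparable across
analyses.

### GREML

Univariate: y = μ1 + g + e, g ~ N(0, v_g G), e ~ N(0, v_e I). After an
eigendecomposition G = UDU′ the REML likelihood separates; h² is profiled
on [0, 1] (41-point grid, then bounded Brent refinement to xatol 1e-8,
with explicit boundary evaluation). The h² standard error is the inverse
square root of the negative numerical curvature of the profile REML
log-likelihood (central differences, step 1e-4); boundary optima are
flagged non-converged and get no SE. The eigen-form log-likelihood carries
full constants and is verified against a direct dense evaluation
(`dense_reml_loglik`) to 1e-6 in the tests.

Bivariate: per-eigenvalue 2×2 blocks Σ_i = d_i V_g + V_e, V_g and V_e
optimised through Cholesky factors with log-diagonals (Nelder–Mead from an
equal-split start ± 0.3, max 2000 iterations); r_g = V_g12/√(V_g11 V_g22),
clipped to [−1, 1] with the clip flagged. Fits use the complete-case
intersection of lines observed for both traits. **Degenerate input:** if
the two phenotype vectors are numerically collinear (|r| > 1 − 1e-10) the
2×2 likelihood is unbounded (the difference component has zero variance),
so the model reduces to the univariate fit and returns r_g = ±1 with both
heritabilities equal to the univariate estimate. No r_g standard error is
reported; the convergence flag stands in.

Averaging: within-element averages are unweighted means of r_g across
environment pairs; between-element averages are unweighted means across
trials; non-converged estimates are excluded. Grouping: average-linkage
hierarchical clustering on distance 1 − r_g cut at k = 2, deterministic
relabelling (the first element's cluster is group 1), manual overrides
applied last and recorded.

### Mixed-model association scan

y = μ + xβ + α + ε with α ~ N(0, λτ⁻¹G). One eigendecomposition per
analysis turns every REML evaluation into weighted least squares. The
default mode re-estimates λ per SNP (exact mixed model): a 62-point grid
(0 plus 61 log-spaced points in [1e−5, 1e5]) followed by 40 iterations of
per-SNP vectorised golden-section refinement on log λ, keeping whichever
of grid/refined λ has the higher REML log-likelihood. `null_lambda` mode
reuses the intercept-only λ̂ for all SNPs — a fast approximation that is
exact under the null and used for the large calibration experiments. The
test is Wald with a Student-t reference on n − 2 df. Monomorphic SNPs are
emitted as flagged null records (β = 0, p = 1) so the t-matrix stays
rectangular.

### Meta-analysis

χ²_i = t_i′ V⁻¹ t_i with t = β/se(β) signed to the alt allele, and V the
Pearson correlation of t-columns over SNPs (pairwise-complete). Default
uses all SNPs for V; an optional trim quantile masks large |t| per column
first. Per SNP, t and V are restricted to the analyses where the SNP has
an estimate; V restrictions are inverted by Moore–Penrose pseudo-inverse
with eigenvalues below 1e-10 × max treated as zero and df = rank. p-values
are the upper chi-square tail at that df. Significance is Bonferroni
(α/m). QTL clustering is lead-based: the most significant unassigned SNP
on a chromosome seeds a cluster and absorbs every significant SNP with
genotypic r² above 0.5 with the *lead* (not nearest-member chaining),
which is deterministic and matches lead-SNP reporting conventions.

## The synthetic-data generator

The generator produces the study conditions the analysis assumes:

* **Genotypes** — fully homozygous inbred lines. Per chromosome,
  `n_founders = 30` founder haplotypes are Markov mosaics of fresh
  Bernoulli(p_j) alleles, p_j ~ U(0.1, 0.9), with per-interval retention
  exp(−d/ld_scale); each line is a Markov mosaic over founder identities
  with the same scale, doubled to dosage {0, 2}. Allele correlation decays
  approximately as exp(−2d/ld_scale), so r² ≈ exp(−4d/ld_scale) reaches a
  ~1/n background near d ≈ ld_scale. The default `ld_scale = 7 Mb` was set
  from this closed form (and confirmed by one simulation) so the decay
  curve crosses the background LD around 7 Mb — the block scale of the
  germplasm being emulated. Missing calls are uniform at `missing_rate`;
  SNPs below `maf_min` realised MAF are dropped. cM positions are bp/4.5 Mb
  and are reporting-only.
* **Architecture** — 13 elements in two groups (Ca/Co/K/Na vs the rest,
  with B assigned to group two). Shared QTL load on two group factors with
  correlation r_between/r_within, giving expected within-group genetic
  correlation 0.45 and between-group −0.20 (defaults echo the study
  conditions); private QTL are element-exclusive; antagonistic QTL have
  strictly opposite signs between groups. Effects are rescaled per element
  so the line genetic variance is h²/(1 − h²) with unit plot residual —
  default h² = 0.42.
* **Trials** — randomised complete blocks (2 reps), optional line subsets
  (the default six-environment plan puts all lines in two trials and a
  200-line subset in four, with per-environment genetic-value scalers
  0.8–1.05 as a coarse G×E surrogate). Plot value = genetic value ×
  env scaler + rep effect (SD 0.2) + a smooth quadratic row/column surface
  (SD 0.3) + iid residual (SD 1.0). No AR1×AR1 residual correlation is
  simulated, matching the BLUE model.

What passing tests on this generator do **not** show about real data:
array genotyping artefacts (non-random missingness, multi-allelic or
paralogous probes), selection and pedigree structure, coalescent LD
heterogeneity, non-scalar genotype-by-environment interaction, and
autocorrelated field residuals.

## Problem sizes used by the acceptance checks

Chosen to keep the full suite and acceptance script each inside a few
minutes on one CPU while leaving Monte-Carlo error well below the stated
tolerances: mixed-model/REML oracles at n = 30–50 lines; null calibration
at 300 lines × 10,000 SNPs × 26 analyses; h²/r_g recovery at 500 lines ×
2,000 SNPs × 20 draws; power ordering at 200 lines × 300 SNPs × 50 seeds
(QTL effect 0.4 phenotypic SD per allele copy, polygenic h² = 0.3);
end-to-end heritability at 300 lines, 4 elements, one 2-rep trial; LD
block size at 300 lines × 600 SNPs on two 100 Mb chromosomes.

## Numerical and degenerate-case notes

* All TSVs use '.' for undefined values; coordinates are 1-based bp.
* Every stochastic operation derives its generator from
  `(seed, operation-name)`; same seed ⇒ bit-identical outputs.
* Loess: local quadratic with tricube weights on the nearest span-fraction
  (default span 0.5, widened automatically below 10 points per window);
  the local abscissa is scaled by the bandwidth for conditioning; fitted
  values are clipped at 0.
* Quantiles use the linear-interpolation convention (numpy default) —
  stated because quantile definitions differ across tools.
* Block size is linearly interpolated between the straddling grid points;
  a curve that never reaches the background yields NaN and is reported as
  "not reached"; a curve starting below it yields 0.
* LD-kNN ties: neighbour ties break by line order; vote ties toward the
  lower dosage; SNPs with no usable donors fall back to the modal dosage
  and are counted in the report.
* In the imputation LD ranking, missing cells are mean-filled *only* for
  ranking the top-l partners; distances and votes are missing-aware.

## Null-calibration behaviour

With V estimated from the same SNPs, the per-dataset mean of χ² is exact
by construction. The empirical distribution of the 10,000 p-values in one
dataset is, however, conditioned on just 26 phenotype realisations, so
uniformity statistics (e.g. a KS test) fluctuate across datasets more than
iid sampling suggests, while the rejection rate at α = 0.05 stays within
0.044–0.047 in the experiments the suite runs. Interpret single-dataset
uniformity metrics accordingly.

## Known limitations

* Wald tests only (no LRT/score); no genomic-control correction.
* No covariates beyond the intercept in the scan.
* Bivariate REML only (no >2-trait models); no r_g standard errors.
* PLINK text round-trips recover allele roles alphabetically (the .ped
  format does not store them).
* The pipeline's BLUE stage is quadratic-to-cubic in plots per trial;
  panels of tens of thousands of plots per trial would need a sparse
  implementation.
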