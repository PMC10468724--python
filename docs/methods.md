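# Methods

## Model

All stages share one linear mixed model for *n* individuals,

    y = X β + u + ε,   Var(u) = σ²_g K,   Var(ε) = σ²_e I,

where `y` is the reproductive index (a continuous [0, 1] phenotype),
`X` holds the intercept and any fixed-effect covariates (farm and
calving season as treatment-coded dummies, plus SNP cofactors during
multi-locus scanning), and `K` is the Gower-centered VanRaden genomic
relationship matrix.  The incidence matrix of the random effect is the
identity: each individual carries its own additive genetic merit.

### Kinship

`compute_grm` builds VanRaden method 1: dosages are mean-imputed per
SNP, columns centered at twice the in-sample allele frequency, and
G = WW′ / (2Σⱼpⱼ(1−pⱼ)).  `gower_scale` double-centers
(J = I − 11′/n) and rescales so trace(G*) = n − 1; the target trace is
configurable.  Gower centering makes the variance components live on
the phenotypic scale and is idempotent and invariant to any positive
rescaling of the input.  A monomorphic-only panel is an error.
Downstream factorizations use the eigendecomposition of K, cached on
the `Grm` object.

### REML (EMMA)

`emma_reml` profiles the restricted likelihood down to the variance
ratio δ = σ²_e/σ²_g.  With A an orthonormal basis of the complement of
col(X), the spectrum (ξᵢ, ηᵢ) of A′KA rotates the problem so the
restricted log-likelihood and its score are scalar functions of δ.
The score is evaluated on 100 log-spaced intervals spanning
δ ∈ [1e−5, 1e5] (both bounds and the resolution are arguments); every
sign-change bracket is refined by Brent root finding and the global
optimum among stationary points and the two endpoints is returned.
σ²_g is floored at 1e−12 so h² = σ²_g/(σ²_g+σ²_e) is always defined.

The variance of h² is obtained by the delta method: the observed
information of the restricted likelihood in (σ²_g, σ²_e) is formed
analytically in the rotated basis, inverted, and sandwiched with
∇h² = (σ²_e, −σ²_g)/(σ²_g+σ²_e)².  The reported SE is the square root
of that variance.  Other estimators exist (expected information,
profile intervals); the observed-information version is the package's
choice and is isolated in one function.

### Single-locus scan (EMMAX)

Variance components are estimated once under the null design and held
fixed across markers.  One rotation into the GRM eigenbasis with
weights wᵢ = σ²_g λᵢ + σ²_e turns every per-SNP fit into ordinary
least squares; each marker is tested by a two-sided t-test on its GLS
coefficient with n − rank([X, g]) degrees of freedom (a chi-square
variant is available; the t-test matters at small n).  Markers with
zero variance after imputation are emitted flagged, with p = 1 and
β = 0, rather than dropped, so row counts stay reconcilable.

The per-marker Mahalanobis RSS — the squared norm of the rotated,
variance-standardized residuals, i.e. the GLS objective — is recorded
for every model and for the null, because the multi-locus posterior
criterion consumes it.

PVE is reconstructed as β²·2p(1−p)/(σ²_g+σ²_e): the numerator is the
marker's additive variance under Hardy–Weinberg proportions and the
denominator the model's phenotypic variance.  This reproduces the
magnitude relation between reported effect sizes and PVEs (back-solving
the largest reported QTL's β = −0.0188, PVE = 0.0110 and
σ²_g+σ²_e = 0.0127 gives a feasible heterozygosity 2pq ≈ 0.395), but
the formula is a reconstruction, so it is isolated in `snp_pve`.

Genomic inflation uses the pseudo-lambda form
log₁₀(median observed P)/log₁₀(0.5), which equals 1 exactly when the
median p-value is 0.5.

### Multi-locus stepwise scan

Forward inclusion adds the most significant SNP of the current scan as
a fixed-effect cofactor (ties broken by SNP id), re-estimates the
variance components from scratch with the cofactors in the design, and
rescans the remaining markers; after `n_forward` steps (default 10)
backward elimination removes, per step, the cofactor with the largest
drop-one re-test p-value until one remains — giving `n_forward − 1`
backward records.  No warm starts: every step's REML is independent,
which keeps the path exactly reproducible.

Six optimality criteria are recorded per step, with p the full
parameter count (intercept, δ, covariates, cofactors), q the
cofactor-free count, and m the markers tested in that step:

* BIC = −2 l_F + p log n, where l_F is the unrestricted Gaussian
  log-likelihood at the REML variance components and GLS fixed
  effects;
* EBIC = BIC + 2 log C(n, p−q), the combinatorial term (via
  log-gamma) pricing the size of the search space;
* MBIC = BIC + 2p log(m/2.2 − 1), requiring m > 3;
* Bonferroni (forward only): best p-value of the preceding scan below
  1/(20m);
* multiple Bonferroni: every cofactor's drop-one p-value below
  1/(20m);
* MPPA: every cofactor's posterior probability of association at
  least 0.5, with bf = exp((n log(mrss_h0/mrss_k) − log n)/2),
  prior 1/m, posterior odds bf·pr/(1−pr), and pp = po/(1+po), all in
  log space.

Two readings that the criteria definitions leave open are pinned down
here as package choices: the Bayes-factor parenthesization above is
the standard BIC-approximation form for one added parameter (the
alternative outer reading is available behind a flag), and the forward
Bonferroni threshold reuses the 1/(20m) constant stated for the
multiple-Bonferroni criterion.  `optimal_models` selects, per
criterion, the minimizing step (information criteria) or the step with
the most cofactors satisfying the condition (threshold criteria), ties
toward fewer cofactors, step 0 when nothing qualifies.  The per-step
h² reported is that of the fitted model with the cofactors in the
design.

### QTL calling

Significant SNPs (P ≤ 5e−05 by default, the polygenic-trait threshold;
−log₁₀P = 4.30) are clustered greedily, most significant first: a lead
absorbs every unassigned significant SNP on its chromosome within
±1 Mb, and clusters of at least three members (lead + ≥ 2 supporters)
become QTL, labelled `chr_Mb` with the lead position rounded to the
nearest Mb.  The alternative fixed-bin reading ("the same 1 Mb
interval") is available via `window_mode='bin'`; the two differ only at
bin edges.  If the lead is a cofactor its own scan statistics are
degenerate, so the reported PVE is the maximum over the supporters.
Consumed-but-small clusters are not revisited, making the output
independent of input row order.

### GBLUP and cross-validation

`fit_gblup` estimates variance components by EMMA, fixed effects by
GLS, and breeding values by û = σ²_g K V⁻¹(y − Xβ̂).  Allele
substitution effects come from the overall-normalized marker matrix:
columns centered at 2pⱼ and one global constant √(2Σpⱼ(1−pⱼ)), so that
MM′ equals the VanRaden G; then α = M′(MM′ + εI)⁻¹û with a 1e−8 ridge,
and û = Mα to numerical precision.  On a raw (non-Gower) GRM this is
exactly ridge-regression SNP-BLUP with shrinkage δ = σ²_e/σ²_g, which
the tests verify against an independent implementation.

Cross-validation computes the GRM once from all samples, randomly
partitions them into k folds per iteration (k = 3, 10 iterations by
default), trains on each fold's complement — the validation phenotypes
are never read — and predicts ŷ_v = X_v β̂ + û_v with
û_v = σ²_g K_vt V_t⁻¹(y_t − X_t β̂).  Per fold it reports Pearson r
(n−1 denominators), RSS, TSS, R² = 1 − RSS/TSS, RMSE = √(RSS/n), MAE,
and the predictive ability corr(û_v, y_v).  Summary means and SDs are
taken over all k·iterations fold-level values (the aggregation level
is a package choice).  Prediction accuracy divides the mean ability by
√h² from a whole-data fit under the same covariate specification; the
square-root form is adopted because it reproduces the reported
identity 0.2301/√0.2550 = 0.4557.

## Quality control

Samples are filtered first (call rate < 0.90 excluded), then SNPs in
the order call rate (> 0.15 missing) → MAF (< 0.01, from non-missing
calls) → HWE (exact conditional test, P < 1e−25), with every SNP
statistic computed on the post-sample-filter matrix; a SNP failing
several rules is attributed to the first.  All inequalities are
strict, matching the stated thresholds.  The exact test enumerates the
conditional distribution of heterozygote counts in log space and sums
probabilities no larger than the observed one, so p-values far below
1e−25 (even below the smallest positive double, via
`hwe_log10_pvalue`) are resolved without underflow; a chi-square
variant exists behind a flag since the original test's form is not
stated.

## Synthetic data

`simulate_genotypes` draws haplotypes per LD block: all SNPs in a
block share a target MAF drawn from [maf_low, maf_high]; each SNP
copies the previous SNP's allele with probability 1 − r (r = 0.1 by
default) and redraws from the block MAF otherwise.  Copy-with-mutation
preserves the marginal allele frequency exactly while giving adjacent
markers a haplotype correlation of 1 − r, so realized MAFs stay inside
the sampling band and LD is tunable without coalescent machinery.
Genotypes are the sum of two independent haplotypes (HWE within
blocks); missing calls are injected uniformly at random — the simplest
model compatible with the downstream call-rate filters.  Blocks never
span chromosome boundaries (5 chromosomes, 25 kb spacing by default).

`simulate_study` builds a liability = farm + season + QTL + polygenic
+ residual.  Farm and season effects are Gaussian with SD 0.25 across
16 farms and 4 seasons — matching the herd structure of the motivating
design and giving a covariate variance fraction near 0.12.  Causal
SNPs are spread across the panel at even quantiles among markers with
MAF ≥ 0.1; each explains `qtl_pve_each` of the liability variance net
of fixed effects, the polygenic term (random weights over all other
markers) supplies the remainder of `h2_target`, and the realized
genetic fraction is pinned exactly by rescaling the genetic component
and orthogonalizing the residual against it — so recovery tests
measure estimator error, not generator noise.  The liability is
standardized to unit variance and mapped through the logistic
function, keeping the index in (0, 1) like a predicted probability.

Because the logistic map is mildly nonlinear over a unit-variance
liability, the *index-scale* linear heritability sits slightly below
the liability target (analytically ≈ 0.246 for a 0.25 target under the
default fixed-effect structure); REML estimates from the index inherit
that small attenuation.  What passing recovery tests show is that the
estimator tracks the index-scale genetic signal without bias at the
stated tolerance; they do not show that real reproductive-index data
have any particular heritability, nor do the simulated panels
reproduce coalescent LD decay, pedigree structure, or the nine health
events behind the original epidemiological index — all out of scope.

`tail_select` retains, within every farm × season cell, the top
⌊high_fraction·n⌋ and bottom ⌊low_fraction·n⌋ individuals by index
value (defaults 15% and 7.25%, the motivating design's sampling
fractions), with ties broken by individual id; cells that retain
nothing are skipped with a logged warning.  The per-stratum base
counts of the original design are not published, so fractions and
totals are free parameters rather than fixed constants.

## Numerical choices and degenerate inputs

* δ grid: 100 log-spaced intervals on [1e−5, 1e5]; Brent refinement at
  xtol 1e−12.  Boundary optima are returned as-is (pure-noise
  phenotypes land near the upper δ bound, i.e. h² ≈ 0).
* GRM eigendecompositions use symmetric `eigh`; projected eigenvalues
  are clipped at zero before adding δ.
* The ASE back-solve ridge (1e−8) only stabilizes MM′; it never enters
  the mixed-model V.
* Rank-deficient designs, non-finite phenotypes, constant truth
  vectors in the metric suite, monomorphic panels, and truncated or
  mislabeled PLINK files all raise errors naming the offending input;
  constant *predictions* only void the correlation (NaN with a
  warning) since the other five metrics remain defined.
* PLINK bed I/O is SNP-major with allele 1 = minor allele, so dosages
  count minor-allele copies; the reader validates magic bytes and the
  byte length implied by the fam/bim dimensions.
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); reruns are byte-identical.

## Test and acceptance problem sizes

The suite checks exact oracles at dense-solvable sizes (n ≤ 30),
statistical properties at n = 300–800 with fixed seeds, and the
headline recovery at n = 1500, m = 5000 over 20 replicates; the
acceptance script uses the same sizes, with null calibration at
n = 800, m = 2000 and cross-validation at n = 800.  These sizes are
the package's chosen trade-off between discriminating power and a
test suite that runs in minutes on one CPU.
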