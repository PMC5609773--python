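# Methods

## Model

A triplet is an ordered trio (G, E, C): a biallelic SNP dosage
G ∈ {0,1,2}, a gene's expression E (log₂ cpm, covariate-residualized) and
a continuous phenotype C (natural-log transformed, covariate-residualized,
right-skewed on the raw scale). Assuming acyclicity and that G associates
with E and E with C, four factorizations are possible (causal, colliding,
reactive, independent; see README). Each conditional factor is a Gaussian
linear regression whose maximized log-likelihood has the closed form
−(n/2)(ln 2π + ln σ̂²_MLE + 1); the P(G) factor is identical across the
four factorizations, cancels in every AIC comparison, and is omitted, so
the parameter counts are 6/6/6/7. Closed-form OLS-based maximization is
the production path; direct numerical maximization of the written-out
likelihoods (BFGS over coefficients and log-variance) is retained as a
test oracle and agrees to better than 1e-6.

**Direction versus global minimum.** The saturated independent model
nests both directional models, so under a true directional model it
overtakes the truth whenever the extra edge's likelihood-ratio statistic
(asymptotically χ²₁) exceeds 2 — about 16% of the time at any effect
size. The *claimed direction* between E and C therefore rests on
Δ_AIC_ = |AIC_causal − AIC_colliding|, not on the four-way argmin; the
global argmin is still reported. Evidence classes: Δ_AIC_ < 2
inconclusive, [2, 10) moderate, ≥ 10 strong (relative likelihood
1 − e⁻⁵ > 0.99). Δ_AIC_ is taken as an absolute value.

**Partial-correlation check.** The selected direction must reproduce its
d-separation pattern at level α = 0.05: causal needs a marginal G–C
association that vanishes given E; colliding needs a G–C association
that appears only given E. Both tests are OLS t-tests of G's coefficient.

**Mendelian randomization.** Colliding candidates (phenotype →
expression) are confirmed by TSLS with GWAS instruments for the
phenotype: stage 1 projects the residualized phenotype onto the
instrument dosages, stage 2 regresses residualized expression on the
projection; the SE uses stage-2 residuals formed from the original
exposure. The first-stage F is reported and F < 10 triggers a warning
(never an error — instrument strength is a property of the data, not a
filter). Summary-level alternatives: IVW (precision-weighted mean of
Wald ratios, identical to the zero-intercept weighted regression of
outcome betas on exposure betas) and MR-Egger (free intercept estimating
directional pleiotropy; instruments oriented to non-negative exposure
betas; t-inference on m − 2 df). Causal candidates are instead checked
for a significant SNP–phenotype association in the published summary
statistics. A pipeline *final call* requires Δ_AIC_ ≥ 10 AND a passing
partial-correlation check AND MR significance at α.

**Power.** With an instrument explaining r² of the exposure and a
standardized causal effect β, the instrument–outcome variance explained
is R²_GY = r²·β² and the normal approximation for a correlation test
gives n = ⌈(z₁₋α/₂ + z_power)²/R²_GY⌉ — about 15,700 at r² = 0.05,
β = 0.1, α = 0.05, 80% power. A Monte-Carlo check (2,000 replicates of
the Fisher-z correlation test at exactly that n) reproduces the target
power within sampling error.

## Pipeline parameters (defaults, units, rationale)

| parameter | default | meaning |
|---|---|---|
| `maf_min` | 0.05 | minimum minor-allele frequency (non-missing denominator) |
| `missing_max` | 0.01 | maximum per-variant missing-call fraction |
| `ld_window`/`ld_step`/`ld_r2_max` | 50 / 5 / 0.5 | greedy sliding-window LD pruning, window measured in *variants* (the window semantics of the standard pruning tools) |
| `relatedness_threshold` | 0.1 | GRM off-diagonal above which samples are grouped; one kept per connected component (highest call rate, then input order) |
| `cpm_min`/`min_samples_expressed` | 1 / 10 | gene kept iff cpm > 1 in at least 10 samples (raw library sizes) |
| `n_genotype_pcs` | 4 | genotype PCs (computed on the LD-pruned set) as population-structure covariates |
| `expression_pc_kmax` | 10 | expression PCs considered; the selected set is the prefix preceding the first PC associated with the phenotype at α (so phenotype signal is never regressed out) |
| `cis_window` | 250,000 bp | SNP-to-gene-body distance, inclusive, gene-span anchored |
| `fdr` | 0.05 | BH FDR for the phenotype-association stage |
| `n_perm` | 10,000 (full runs); 1,000 in tests | per-gene permutations for the Gumbel calibration |
| `alpha` | 0.05 | nominal level for partial-correlation, stepwise entry (Bonferroni-scaled) and MR gates |
| `delta_aic_strong` | 10 | candidate gate (relative likelihood > 0.99) |

Numerical conventions: PCs are SVD-based with each component's
largest-magnitude loading made positive (reproducible signs); missing
dosages are mean-imputed inside PCA, GRM and GRS (expected dosage
2·frequency) but dropped pairwise in association scans; TSLS requires a
non-flat first stage and errors otherwise; Gumbel fits reject degenerate
permutation samples; dosages are always oriented so the counted allele
is the minor allele (an idempotent reflection).

**Relatedness guard.** The GRM off-diagonal for unrelated samples has
sampling SD ≈ 1/√m over m variants. When m < 9/threshold² (900 at the
default 0.1) noise alone would chain unrelated samples into spurious
components, so the filter skips with a warning; genome-scale inputs are
far above this bound, and `min_variants` overrides it.

**Permutation scheme.** Permutations shuffle the covariate-residualized
expression vector, keeping genotypes and the covariate structure fixed.
For the vectorized rescan, missing dosages are mean-imputed, while the
degrees of freedom use the minimum per-SNP non-missing count among the
gene's cis SNPs — the per-permutation best SNP is not tracked, so the df
of the most-missing SNP keeps the transform conservative. The gene-level
p is the fitted Gumbel survival of −log₁₀(p_nominal), which (unlike the
empirical rank) is not floored at 1/n_perm. Stepwise eQTL extraction
enters SNPs by smallest conditional p while that p is below the same
Bonferroni threshold used in the marginal scan (0.05/N genes tested);
the marginal scan's threshold is reused because no separate stopping
rule is more defensible a priori.

## Synthetic data: what it emulates and what it does not

- **Genotypes**: biallelic HWE SNPs; LD by a Gaussian copula whose latent
  correlation is solved numerically so the *dosage* correlation matches
  the requested value (thresholding attenuates latent correlation; pairs
  with very different MAFs cannot reach high r — the Fréchet bound — and
  are clipped at their maximum). No realistic human LD maps or
  population structure beyond what PCs are meant to absorb.
- **Counts**: negative binomial (gamma–Poisson) with log-normal baseline
  abundances, uniform library sizes, optional batch log₂ mean-shifts,
  and signals injected on the log₂-mean scale so the log-cpm pipeline
  sees approximately linear effects. No gene–gene correlation beyond
  batch, no GC/length biases, no read-level artifacts.
- **Phenotype**: built on the natural-log scale from a genetic score,
  mild covariate effects and Gaussian noise, so the raw phenotype is
  log-normal (right-skewed).
- **Triplets**: ancestral sampling of the declared DAG with path
  coefficients applied to variance-standardized parents and unit
  residual SD — "effect 0.5" is 0.5 residual-SD per parent SD, giving
  marginal correlations β/√(1+Σβ²). A fifth, adversarial `confounded`
  scenario (latent common cause of E and C, plus a real eQTL) is included
  because it fools the likelihood stage by design; only the MR gate
  rejects it.

Passing tests on these generators demonstrates internal correctness and
calibration of every stage under the model's own assumptions; they do
not certify behaviour under misspecification real data can show
(non-Gaussian residuals, cryptic relatedness, widespread pleiotropy,
expression networks).

## Study conditions used by the validation battery

Simulation sizes are chosen to mirror the analysis regime the method
targets while keeping the battery runnable in minutes on one CPU:

- Model recovery: 100 triplets per generative model, n = 491, effects
  0.5. Directional recovery is scored (see "Direction versus global
  minimum"); the four-way argmin diagonal is also reported, whose
  theoretical ceiling is P(χ²₁ < 2) ≈ 84%.
- Likelihood oracle: 50 random triplets (n = 200), agreement < 1e-6.
- Permutation calibration: 50 genes × 20 cis SNPs, n = 300; eQTL effects
  spread so the empirical gene-level p covers [0.001, 0.5]. The
  agreement sweep uses 10,000 permutations — resolving p ≈ 0.001 to a
  factor of two needs a permutation count well beyond 1/p — and judges
  each gene's factor-2 agreement against the empirical p's own
  exact-binomial 99% CI (the comparator is itself a Monte-Carlo
  estimate; a 10×-miscalibrated p still fails), with the raw median
  ratio additionally required inside (0.5, 2). A second, fully null set
  of 50 genes at 1,000 permutations feeds the uniformity KS test.
- MR recovery: TSLS at n = 5,000 with 16 instruments sized for
  first-stage F ≈ 20 (near-weak instruments, F ≈ 10, visibly bias 2SLS
  toward OLS and are exactly what the F-warning exists for); IVW and
  Egger on 16-instrument summary sets (effect 0.2, pleiotropy 0.02);
  specificity on a confounded null at n = 491 with instruments at
  GRS-scale strength (R² ≈ 0.10 of the exposure — much weaker
  instrument sets at this n enter the many-weak-instrument regime and
  distort the 2SLS test size).
- End-to-end: 100 signal and 100 null cohorts, each n = 491, 200 genes,
  3 cis SNPs per gene, 16 instruments jointly explaining 10% of the
  phenotype (sized with the package's own power formula so the MR gate
  has ≈ 90% power at n = 491 given the expression effect), eQTL and
  phenotype→expression effects of 0.35 log₂ units (≈ 0.5–0.7 SD of
  log-cpm at dispersion 0.1), batch SD 0.1, GWAS n = 80,000; 1,000
  permutations per gene.

## Known limitations

- Gaussian likelihoods throughout; heavy-tailed expression residuals can
  distort AIC gaps.
- No empirical-Bayes variance moderation in the association stage: plain
  WLS t-tests, asymptotically equivalent at cohort sizes in the
  hundreds, exact contracts, but less powerful for very small n.
- The genotype is treated as a fixed additive regressor; dominance or
  haplotype effects are out of scope, as are >3-node networks and cyclic
  models.
- The two Markov-equivalent orientations of the saturated model cannot
  be distinguished, by construction.
- Summary-statistic imputation for instruments missing from the GWAS is
  not provided (needs an external LD reference panel); such instruments
  must be dropped or proxied upstream.
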