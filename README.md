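# triplemr

Causal triplet model selection with Mendelian-randomization confirmation
for cohorts with genotypes, RNA-seq expression and a continuous blood
phenotype.

## The problem

Differential-expression analysis of a trait like C-reactive protein (CRP)
yields hundreds of correlated genes, but correlation says nothing about
whether the trait drives expression, expression drives the trait, or an
unmeasured confounder drives both. When each gene also has a *cis*-eQTL —
a nearby SNP G that perturbs its expression E — the genotype acts as a
natural anchor: under acyclicity, the joint distribution of the triplet
(G, E, phenotype C) can only factorize four ways:

- **causal**: P(G)·P(E|G)·P(C|E) — expression drives the phenotype,
- **colliding**: P(G)·P(C)·P(E|G,C) — the phenotype drives expression,
- **reactive**: P(G)·P(C|G)·P(E|C) — the SNP acts through the phenotype,
- **independent**: P(G)·P(E|G)·P(C|G,E) — the saturated model.

Each Gaussian conditional factor is maximized in closed form and models
are compared by AIC = 2k − 2·log L. Evidence for a direction between E
and C is graded by Δ_AIC_, the gap between the causal and colliding fits:
Δ_AIC_ ≥ 10 corresponds to relative likelihood 1 − e⁻⁵ > 0.99 for the
better model. Because likelihood selection can be fooled by unmeasured
confounding, surviving triplets must also pass the d-separation
(partial-correlation) pattern their model implies, and finally a
Mendelian-randomization (MR) estimate — two-stage least squares with GWAS
instruments, or summary-level IVW/MR-Egger — must independently confirm
the effect. A pipeline discovery requires all three gates.

The pipeline stages are: genotype/expression QC (MAF ≥ 0.05, missingness
≤ 0.01, LD pruning, relatedness removal, cpm > 1 in ≥ 10 samples) →
TMM + log-cpm + voom precision weights → per-gene weighted regression on
ln-phenotype with covariates and BH FDR → *cis*-eQTL scan (±250 kb) with
Gumbel-calibrated permutation p-values and per-gene Bonferroni (0.05/N) →
stepwise-independent eQTL extraction → triplet AIC selection → partial
correlation → MR.

Because the individual-level cohorts such an analysis targets cannot be
redistributed, the package ships a first-class synthetic-data module
(`triplemr.synthetic`) that generates HWE genotypes with LD blocks,
negative-binomial counts, a right-skewed phenotype, GWAS-scale instrument
summary statistics, and triplets drawn from each causal structure — so
every stage has a parameter- or model-recovery test with known truth.

## Worked example

Generate a synthetic cohort in which exactly one of 200 genes responds to
the phenotype (the colliding structure: the gene has a cis-eQTL *and* the
phenotype shifts its expression), then run the full pipeline:

```python
from triplemr import simulate_cohort, run_study

cohort = simulate_cohort(seed=8)          # n=491, 200 genes, 16 instruments
res = run_study(cohort.genotypes, cohort.expression, cohort.samples,
                cohort.sumstats, params={"n_perm": 1000}, seed=8)
print(res.stage_counts)
print(res.final_calls)
```

prints

```
{'variants_in': 616, 'samples_in': 491, 'genes_in': 200,
 'variants_qc': 616, 'samples_qc': 491, 'genes_expressed': 200,
 'genes_associated': 1, 'cis_pairs': 3, 'eqtl_hits': 2,
 'genes_with_eqtl': 1, 'independent_eqtls': 1, 'triplets': 1,
 'triplets_informative': 1, 'triplets_strong': 1, 'candidates': 1,
 'final_calls': 1}
[{'gene_id': 'gene_0000', 'snp_id': 'snp_1_0', 'best_model': 'colliding',
  'direction': 'colliding', 'delta_aic': 16.18..., 'mr_method': 'tsls_multi',
  'mr_beta': 0.388..., 'mr_se': 0.0708..., 'mr_p': 6.5e-08, 'mr_pass': True}]
```

Reading the funnel: of 200 genes, one survives the phenotype-association
FDR gate (`genes_associated`), its cis window holds 3 SNPs of which two
are significant eQTLs collapsing to one independent signal, the
triplet's Δ_AIC_ ≈ 16 favours the colliding model (phenotype →
expression), the partial-correlation pattern matches, and the
16-instrument TSLS confirms a positive causal effect of the phenotype on
that gene's expression — exactly the structure that was simulated.

The same run is available from the shell:

```bash
triplemr simulate --config sim.yaml --out data/
triplemr run --config run.yaml
```

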