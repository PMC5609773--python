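"""Synthetic genotype / expression / phenotype generators with known truth.

Every generator is deterministic under a fixed seed and returns a
machine-readable truth record, so each downstream stage of the analysis
(association, cis-eQTL mapping, triplet model selection, Mendelian
randomization) has a parameter- or model-recovery test.

Genotypes are biallelic SNPs under Hardy-Weinberg equilibrium; linkage
disequilibrium is induced by a Gaussian copula (a latent AR(1) process
within blocks, thresholded at the HWE genotype quantiles) rather than by
haplotype simulation — only pairwise r2 matters to LD pruning and to
stepwise conditional tests. RNA-seq counts are negative binomial with
log-normal baseline abundances, library-size variation and optional batch
mean-shifts; expression signals are injected on the log2-mean scale so the
log-cpm pipeline sees approximately linear effects. The phenotype is
log-normal on the raw scale (right-skewed), modelled on the natural-log
scale throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import (
    ExpressionData,
    GenotypeMatrix,
    SampleTable,
    SummaryStatsTable,
    GENE_COLUMNS,
    VARIANT_COLUMNS,
)

TRIPLET_MODELS = ("causal", "colliding", "reactive", "independent", "confounded")

# which structural effects each generative model allows to be nonzero
_MODEL_EDGES = {
    "causal": ("beta_ge", "beta_ec"),
    "colliding": ("beta_ge", "beta_ce"),
    "reactive": ("beta_gc", "beta_ce"),
    "independent": ("beta_ge", "beta_gc", "beta_ec"),
    "confounded": ("beta_ge", "conf_strength"),
}


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def _binary_corr(latent_r: float, p1: float, p2: float) -> float:
    """Correlation of the two indicators 1{Z_i < Phi^-1(p_i)} under a
    bivariate normal with correlation ``latent_r``."""
    z1, z2 = stats.norm.ppf(p1), stats.norm.ppf(p2)
    joint = stats.multivariate_normal(
        mean=[0.0, 0.0], cov=[[1.0, latent_r], [latent_r, 1.0]]
    ).cdf([z1, z2])
    return (joint - p1 * p2) / np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))


def _latent_corr_for(target: float, p1: float, p2: float) -> float:
    """Latent normal correlation giving indicator (and hence dosage)
    correlation ``target``; clipped to the maximum the frequencies admit."""
    from scipy.optimize import brentq

    hi = 0.9999
    if _binary_corr(hi, p1, p2) <= target:
        return hi
    return float(brentq(lambda r: _binary_corr(r, p1, p2) - target, 0.0, hi, xtol=1e-6))


def simulate_genotypes(
    n: int,
    m: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    ld_block_size: int = 1,
    ld_rho: float = 0.0,
    seed: int = 0,
    chrom: str = "1",
    start_pos: int = 1,
    spacing: int = 1_000,
    missing_rate: float = 0.0,
) -> GenotypeMatrix:
    """Draw ``n`` samples at ``m`` HWE SNPs with optional LD blocks.

    Within a block of ``ld_block_size`` consecutive variants the latent
    Gaussians follow an AR(1) with parameter ``ld_rho``, so adjacent
    dosage correlation is approximately ``ld_rho``; blocks are mutually
    independent.
    """
    if not (0 < maf_range[0] <= maf_range[1] <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    if not (0 <= ld_rho < 1):
        raise ValueError("ld_rho must be in [0, 1)")
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(maf_range[0], maf_range[1], size=m)

    # Thresholding a bivariate normal attenuates correlation, so the latent
    # adjacent correlation is solved per pair to make the *dosage*
    # correlation come out at ld_rho (clipped at what the allele
    # frequencies admit).
    latent_rho = np.zeros(m)
    if ld_rho > 0 and ld_block_size > 1:
        for j in range(1, m):
            if j % ld_block_size != 0:
                latent_rho[j] = _latent_corr_for(ld_rho, mafs[j - 1], mafs[j])

    def latent_chain() -> np.ndarray:
        z = rng.standard_normal((n, m))
        if ld_rho > 0 and ld_block_size > 1:
            for j in range(1, m):
                r = latent_rho[j]
                if r > 0:
                    z[:, j] = r * z[:, j - 1] + np.sqrt(1 - r**2) * z[:, j]
        return z

    dosages = np.zeros((n, m))
    for _ in range(2):  # one allele per haplotype
        u = stats.norm.cdf(latent_chain())
        dosages += (u < mafs).astype(float)
    if missing_rate > 0:
        mask = rng.random((n, m)) < missing_rate
        dosages[mask] = np.nan
    alleles = rng.choice(list("ACGT"), size=(m, 2))
    same = alleles[:, 0] == alleles[:, 1]
    alleles[same, 1] = np.where(alleles[same, 0] == "A", "G", "A")
    variants = pd.DataFrame(
        {
            "id": [f"snp_{chrom}_{i}" for i in range(m)],
            "chrom": chrom,
            "pos": start_pos + spacing * np.arange(m),
            "ref": alleles[:, 0],
            "alt": alleles[:, 1],
        }
    )[VARIANT_COLUMNS]
    sample_ids = [f"S{i:04d}" for i in range(n)]
    return GenotypeMatrix(dosages, variants, sample_ids)


# ---------------------------------------------------------------------------
# triplets
# ---------------------------------------------------------------------------


@dataclass
class TripletScenario:
    """Declared generative model for one (SNP, expression, phenotype) triplet.

    Effects are path coefficients applied to variance-standardized parent
    variables with residual SD ``noise_sd``; with ``noise_sd = 1`` each
    coefficient is an effect in residual-SD units. Only the edges
    consistent with ``model`` may be nonzero.
    """

    model: str
    n: int = 491
    maf: float = 0.3
    beta_ge: float = 0.0  # SNP -> expression
    beta_ec: float = 0.0  # expression -> phenotype
    beta_ce: float = 0.0  # phenotype -> expression
    beta_gc: float = 0.0  # SNP -> phenotype
    conf_strength: float = 0.0  # shared latent confounder loading
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in TRIPLET_MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.n < 10:
            raise ValueError("n must be >= 10")
        if not (0 < self.maf <= 0.5):
            raise ValueError("maf must be in (0, 0.5]")
        allowed = _MODEL_EDGES[self.model]
        for name in ("beta_ge", "beta_ec", "beta_ce", "beta_gc", "conf_strength"):
            if name not in allowed and getattr(self, name) != 0.0:
                raise ValueError(f"{name} must be zero under model {self.model!r}")

    @classmethod
    def standard(cls, model: str, effect: float = 0.5, **kwargs) -> "TripletScenario":
        """Scenario with every edge allowed by ``model`` set to ``effect``."""
        edges = {name: effect for name in _MODEL_EDGES[model]}
        return cls(model=model, **edges, **kwargs)


def simulate_triplet(
    scenario: TripletScenario,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Ancestral sampling of the declared DAG with Gaussian noise.

    Returns dosage vector ``g``, expression ``e``, phenotype ``c`` (both on
    the residualized, covariate-free scale) and a truth record with all
    coefficients.
    """
    s = scenario
    rng = np.random.default_rng(s.seed)
    p = s.maf
    g = rng.choice([0.0, 1.0, 2.0], size=s.n, p=[(1 - p) ** 2, 2 * p * (1 - p), p**2])
    gsd = np.sqrt(2 * p * (1 - p))
    gz = (g - 2 * p) / gsd  # theoretical standardization

    def noise() -> np.ndarray:
        return s.noise_sd * rng.standard_normal(s.n)

    if s.model == "causal":
        e = s.beta_ge * gz + noise()
        ez = e / np.sqrt(s.beta_ge**2 + s.noise_sd**2)
        c = s.beta_ec * ez + noise()
    elif s.model == "colliding":
        c = noise()
        cz = c / s.noise_sd
        e = s.beta_ge * gz + s.beta_ce * cz + noise()
    elif s.model == "reactive":
        c = s.beta_gc * gz + noise()
        cz = c / np.sqrt(s.beta_gc**2 + s.noise_sd**2)
        e = s.beta_ce * cz + noise()
    elif s.model == "independent":
        e = s.beta_ge * gz + noise()
        ez = e / np.sqrt(s.beta_ge**2 + s.noise_sd**2)
        c = s.beta_gc * gz + s.beta_ec * ez + noise()
    else:  # confounded: latent U -> E and U -> C, plus G -> E
        u = rng.standard_normal(s.n)
        e = s.beta_ge * gz + s.conf_strength * u + noise()
        c = s.conf_strength * u + noise()
    truth = {"scenario": asdict(s)}
    return g, e, c, truth


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------


@dataclass
class EmbeddedSignal:
    """A log2-mean expression shift for one gene driven by a sample-level
    variable (a phenotype or a SNP dosage)."""

    gene_index: int
    driver: np.ndarray  # per-sample values; centred internally
    log2_effect: float
    kind: str = "phenotype"  # or "snp"


def simulate_counts(
    n_genes: int,
    n_samples: int,
    libsize_range: tuple[float, float] = (5e6, 15e6),
    dispersion: float = 0.1,
    batch_effect_sd: float = 0.0,
    embedded_signals: Sequence[EmbeddedSignal] = (),
    seed: int = 0,
    base_log2_mean: float = 5.0,
    base_log2_sd: float = 1.5,
    chrom: str = "1",
    gene_spacing: int = 1_000_000,
    gene_length: int = 10_000,
    batches: np.ndarray | None = None,
) -> tuple[ExpressionData, pd.DataFrame]:
    """Negative-binomial RNA-seq counts with optional batch and signals.

    Gene baseline abundances are log-normal across genes; each sample's
    library size is uniform in ``libsize_range``. ``embedded_signals``
    multiply a gene's mean by ``2**(log2_effect * centred driver)``.
    Returns the expression container and a truth table of injected signals.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    rel = 2.0 ** rng.normal(base_log2_mean, base_log2_sd, size=n_genes)
    rel = rel / rel.sum()
    libsize = rng.uniform(*libsize_range, size=n_samples)
    mu = np.outer(rel, libsize)  # genes x samples

    if batches is None and batch_effect_sd > 0:
        batches = (np.arange(n_samples) >= n_samples // 2).astype(int)
    if batch_effect_sd > 0:
        shift = rng.normal(0.0, batch_effect_sd, size=n_genes)
        mu = mu * 2.0 ** np.outer(shift, batches - np.mean(batches))

    truth_rows = []
    for sig in embedded_signals:
        x = np.asarray(sig.driver, dtype=float)
        xc = x - np.nanmean(x)
        xc = np.nan_to_num(xc)
        mu[sig.gene_index, :] *= 2.0 ** (sig.log2_effect * xc)
        truth_rows.append(
            {
                "gene_index": sig.gene_index,
                "gene_id": f"gene_{sig.gene_index:04d}",
                "kind": sig.kind,
                "log2_effect": sig.log2_effect,
            }
        )

    if dispersion < 1e-12:
        counts = rng.poisson(mu)
    else:
        shape = 1.0 / dispersion
        lam = rng.gamma(shape, mu * dispersion)
        counts = rng.poisson(lam)

    genes = pd.DataFrame(
        {
            "id": [f"gene_{i:04d}" for i in range(n_genes)],
            "chrom": chrom,
            "start": 1 + gene_spacing * np.arange(n_genes),
            "end": 1 + gene_spacing * np.arange(n_genes) + gene_length,
        }
    )[GENE_COLUMNS]
    sample_ids = [f"S{i:04d}" for i in range(n_samples)]
    ed = ExpressionData(counts.astype(np.int64), genes, sample_ids)
    return ed, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------


def simulate_summary_stats(
    instruments: pd.DataFrame,
    true_betas: np.ndarray,
    gwas_n: int,
    seed: int = 0,
) -> SummaryStatsTable:
    """Noisy published effect sizes for a set of instrument SNPs.

    ``instruments`` needs columns ``snp_id, effect_allele, other_allele,
    eaf``. On the standardized-trait scale the sampling SE of a per-allele
    effect is ``1 / sqrt(2 * maf * (1 - maf) * gwas_n)``; estimates are
    ``Normal(true_beta, se^2)`` with two-sided normal p-values.
    """
    if gwas_n <= 0:
        raise ValueError("gwas_n must be positive")
    rng = np.random.default_rng(seed)
    eaf = instruments["eaf"].to_numpy(dtype=float)
    maf = np.minimum(eaf, 1 - eaf)
    se = 1.0 / np.sqrt(2 * maf * (1 - maf) * gwas_n)
    beta_hat = np.asarray(true_betas, dtype=float) + se * rng.standard_normal(len(se))
    z = beta_hat / se
    p = 2 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    df = pd.DataFrame(
        {
            "snp_id": instruments["snp_id"].values,
            "effect_allele": instruments["effect_allele"].values,
            "other_allele": instruments["other_allele"].values,
            "beta": beta_hat,
            "se": se,
            "p": p,
            "eaf": eaf,
        }
    )
    return SummaryStatsTable(df)


# ---------------------------------------------------------------------------
# full cohort for the end-to-end pipeline
# ---------------------------------------------------------------------------


@dataclass
class SyntheticCohort:
    """A complete synthetic study: genotypes, counts, sample table,
    instrument summary statistics, and the generating truth."""

    genotypes: GenotypeMatrix
    expression: ExpressionData
    samples: SampleTable
    sumstats: SummaryStatsTable
    truth: dict


def simulate_cohort(
    n: int = 491,
    n_genes: int = 200,
    signal: bool = True,
    snps_per_gene: int = 3,
    n_instruments: int = 16,
    instrument_r2: float = 0.10,
    eqtl_log2_effect: float = 0.35,
    phen_log2_effect: float = 0.35,
    dispersion: float = 0.1,
    batch_effect_sd: float = 0.1,
    gwas_n: int = 80_000,
    seed: int = 0,
) -> SyntheticCohort:
    """Generate the full study the pipeline consumes.

    Each gene carries ``snps_per_gene`` cis SNPs; a separate chromosome
    holds ``n_instruments`` phenotype instruments that jointly explain
    ``instrument_r2`` of the ln-phenotype variance. When ``signal`` is
    true, gene 0 follows the colliding structure: its first cis SNP is an
    eQTL (``eqtl_log2_effect`` log2-cpm per minor allele) and the
    phenotype shifts its log2 mean by ``phen_log2_effect`` per ln-unit —
    the configuration in which only a phenotype-to-expression causal
    effect can generate the observed dependence. All other genes are null.
    """
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=8)

    gene_spacing = 1_000_000
    # cis SNPs: block of `snps_per_gene` per gene, within 50 kb of gene start
    gm_cis = simulate_genotypes(
        n,
        n_genes * snps_per_gene,
        maf_range=(0.1, 0.5),
        ld_block_size=snps_per_gene,
        ld_rho=0.4,
        seed=int(sub[0]),
        chrom="1",
    )
    pos = np.concatenate(
        [
            1 + gene_spacing * i + 10_000 * (1 + np.arange(snps_per_gene))
            for i in range(n_genes)
        ]
    )
    gm_cis.variants["pos"] = pos

    gm_ins = simulate_genotypes(
        n, n_instruments, maf_range=(0.1, 0.5), seed=int(sub[1]), chrom="2"
    )
    gm_ins.variants["id"] = [f"ins_{j}" for j in range(n_instruments)]

    dosages = np.hstack([gm_cis.dosages, gm_ins.dosages])
    variants = pd.concat([gm_cis.variants, gm_ins.variants], ignore_index=True)
    gm = GenotypeMatrix(dosages, variants, gm_cis.sample_ids)

    # covariates
    age = rng.normal(50, 12, n)
    sex = rng.integers(0, 2, n).astype(float)
    bmi = rng.normal(26, 4, n)
    cells = rng.lognormal(0.0, 0.3, size=(n, 7))
    batch = (np.arange(n) >= n // 2).astype(float)

    # phenotype: instruments + mild covariate effects + noise, ln scale
    ins_maf = gm_ins.maf()
    gz = (gm_ins.dosages - 2 * ins_maf) / np.sqrt(2 * ins_maf * (1 - ins_maf))
    w = np.full(n_instruments, np.sqrt(instrument_r2 / n_instruments))
    cov_part = 0.10 * (age - 50) / 12 + 0.10 * (sex - 0.5) + 0.15 * (bmi - 26) / 4
    resid_var = max(1.0 - instrument_r2 - 0.03, 0.05)
    c_ln = gz @ w + cov_part + np.sqrt(resid_var) * rng.standard_normal(n)

    signals = []
    truth: dict = {"signal": bool(signal), "instrument_weights": w.tolist()}
    if signal:
        eqtl_snp = 0  # first cis SNP of gene 0
        signals = [
            EmbeddedSignal(0, c_ln, phen_log2_effect, kind="phenotype"),
            EmbeddedSignal(0, gm.dosages[:, eqtl_snp], eqtl_log2_effect, kind="snp"),
        ]
        truth.update(
            {
                "signal_gene": "gene_0000",
                "eqtl_snp": gm.variants.loc[eqtl_snp, "id"],
                "phen_log2_effect": phen_log2_effect,
                "eqtl_log2_effect": eqtl_log2_effect,
            }
        )

    ed, sig_truth = simulate_counts(
        n_genes,
        n,
        dispersion=dispersion,
        batch_effect_sd=batch_effect_sd,
        embedded_signals=signals,
        seed=int(sub[2]),
        batches=batch.astype(int),
        gene_spacing=gene_spacing,
    )
    ed = ExpressionData(ed.counts, ed.genes, gm.sample_ids)

    data = pd.DataFrame(
        {
            "phenotype_ln": c_ln,
            "phenotype_raw": np.exp(c_ln + 0.5),
            "age": age,
            "sex": sex,
            "bmi": bmi,
            **{f"cell_{k}": cells[:, k] for k in range(7)},
            "batch": batch,
        },
        index=pd.Index(gm.sample_ids, name="sample_id"),
    )
    st = SampleTable(
        data,
        covariates=["age", "sex", "bmi"] + [f"cell_{k}" for k in range(7)] + ["batch"],
    )

    # published instrument effects: per-allele scale, aligned to the minor allele
    true_per_allele = w / np.sqrt(2 * ins_maf * (1 - ins_maf))
    ins_tab = gm_ins.variants.rename(columns={"id": "snp_id", "alt": "effect_allele", "ref": "other_allele"})
    ins_tab["eaf"] = ins_maf
    ss = simulate_summary_stats(
        ins_tab[["snp_id", "effect_allele", "other_allele", "eaf"]],
        true_per_allele,
        gwas_n=gwas_n,
        seed=int(sub[3]),
    )
    truth["signals"] = sig_truth.to_dict(orient="records")
    return SyntheticCohort(gm, ed, st, ss, truth)
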