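"""Mendelian randomization: instruments, TSLS, IVW, MR-Egger and power.

Genetic variants randomly assorted at meiosis serve as instrumental
variables for a modifiable exposure, so the exposure-outcome effect they
imply is protected from the unmeasured confounding that can fool purely
likelihood-based model selection. This module provides

- a genetic risk score (published effect sizes as weights) usable as a
  single strong instrument,
- individual-level two-stage least squares (multi-instrument or GRS),
- summary-level inverse-variance-weighted and MR-Egger estimators,
- per-instrument exclusion-restriction checks and a Kolmogorov-Smirnov
  uniformity test for p-value enrichment,
- funnel-plot data (MAF-corrected instrument strength vs Wald ratio),
- and the sample size required for a target MR power.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypeMatrix, SummaryStatsTable


@dataclass
class InstrumentSet:
    """Per-SNP exposure (published) and outcome (in-sample) effects,
    aligned by snp id and effect allele."""

    snp_ids: list[str]
    exposure_betas: np.ndarray
    exposure_ses: np.ndarray
    outcome_betas: np.ndarray
    outcome_ses: np.ndarray
    maf: np.ndarray

    def __post_init__(self) -> None:
        for name in ("exposure_betas", "exposure_ses", "outcome_betas", "outcome_ses", "maf"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if (self.exposure_ses <= 0).any() or (self.outcome_ses <= 0).any():
            raise ValueError("standard errors must be positive")

    def __len__(self) -> int:
        return len(self.snp_ids)


@dataclass
class MRResult:
    method: str
    beta: float
    se: float
    p: float
    n_instruments: int
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None
    first_stage_f: float | None = None


def align_instruments(
    gm: GenotypeMatrix, sumstats: SummaryStatsTable
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Match summary-stat rows to dosage columns by id and allele.

    Returns (dosage matrix with columns in summary order, aligned betas,
    allele frequencies, snp ids). The published beta's sign is flipped
    when the effect allele matches the dosage's non-counted allele;
    unmatched alleles are an error.
    """
    var = gm.variants.set_index("id")
    cols, betas, freqs, ids, bad = [], [], [], [], []
    for _, row in sumstats.data.iterrows():
        sid = row["snp_id"]
        if sid not in var.index:
            bad.append(sid)
            continue
        j = var.index.get_loc(sid)
        counted, other = var.loc[sid, "alt"], var.loc[sid, "ref"]
        if row["effect_allele"] == counted and row["other_allele"] == other:
            sign = 1.0
        elif row["effect_allele"] == other and row["other_allele"] == counted:
            sign = -1.0
        else:
            bad.append(sid)
            continue
        cols.append(gm.dosages[:, j])
        betas.append(sign * row["beta"])
        freqs.append(row["eaf"] if sign > 0 else 1 - row["eaf"])
        ids.append(sid)
    if bad:
        raise ValueError(f"instruments with unmatched id/alleles: {bad}")
    return np.column_stack(cols), np.asarray(betas), np.asarray(freqs), ids


def grs(gm: GenotypeMatrix, sumstats: SummaryStatsTable) -> np.ndarray:
    """Genetic risk score: weighted dosage sum with published effect
    sizes as weights; a missing dosage contributes its expected value
    ``2 * allele frequency``."""
    G, w, freq, _ = align_instruments(gm, sumstats)
    G = G.copy()
    expected = 2.0 * freq
    inds = np.where(~np.isfinite(G))
    G[inds] = np.take(expected, inds[1])
    return G @ w


def tsls(
    exposure: np.ndarray,
    outcome: np.ndarray,
    instruments_matrix: np.ndarray,
    f_warn: float = 10.0,
) -> MRResult:
    """Two-stage least squares of outcome on instrumented exposure.

    ``exposure`` and ``outcome`` should already be covariate-residualized.
    The SE uses stage-2 residuals formed from the *original* exposure
    (textbook TSLS variance). A first-stage F below ``f_warn`` raises a
    warning, not an error.
    """
    x = np.asarray(exposure, float)
    y = np.asarray(outcome, float)
    Z = np.atleast_2d(np.asarray(instruments_matrix, float))
    if Z.shape[0] != len(x):
        Z = Z.T
    n = len(x)
    Z1 = np.column_stack([np.ones(n), Z])
    # stage 1: project exposure onto instruments
    coef1, *_ = np.linalg.lstsq(Z1, x, rcond=None)
    xhat = Z1 @ coef1
    ssr = np.sum((xhat - x.mean()) ** 2)
    sse = np.sum((x - xhat) ** 2)
    q = Z.shape[1]
    if ssr <= 1e-12 * max(np.sum((x - x.mean()) ** 2), 1e-300):
        raise ValueError("no instrument strength (first stage is flat)")
    fstat = (ssr / q) / (sse / (n - q - 1))
    if fstat < f_warn:
        import warnings

        warnings.warn(f"weak instruments: first-stage F = {fstat:.2f} < {f_warn}")
    # stage 2 on [1, xhat]
    X2 = np.column_stack([np.ones(n), xhat])
    coef2, *_ = np.linalg.lstsq(X2, y, rcond=None)
    beta = coef2[1]
    # TSLS variance: residuals from the ORIGINAL exposure
    resid = y - (coef2[0] + beta * x)
    df = n - 2
    s2 = resid @ resid / df
    cov = s2 * np.linalg.pinv(X2.T @ X2)
    se = float(np.sqrt(cov[1, 1]))
    p = float(2 * stats.t.sf(abs(beta / se), df))
    method = "tsls_grs" if q == 1 else "tsls_multi"
    return MRResult(method, float(beta), se, p, q, first_stage_f=float(fstat))


def instrument_exclusion_check(
    instruments_matrix: np.ndarray,
    exposure: np.ndarray,
    outcome: np.ndarray,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Exclusion-restriction check: each instrument's coefficient in OLS
    of outcome on (instrument, exposure) should be null; pass iff
    p >= alpha."""
    Z = np.atleast_2d(np.asarray(instruments_matrix, float))
    if Z.shape[0] != len(exposure):
        Z = Z.T
    n = len(exposure)
    rows = []
    for j in range(Z.shape[1]):
        X = np.column_stack([np.ones(n), Z[:, j], exposure])
        coef, *_ = np.linalg.lstsq(X, outcome, rcond=None)
        resid = outcome - X @ coef
        df = n - 3
        s2 = resid @ resid / df
        se = np.sqrt(s2 * np.linalg.pinv(X.T @ X)[1, 1])
        p = 2 * stats.t.sf(abs(coef[1] / se), df)
        rows.append((j, float(coef[1]), float(se), float(p), bool(p >= alpha)))
    return pd.DataFrame(rows, columns=["instrument", "beta", "se", "p", "pass"])


def ivw(instrument_set: InstrumentSet) -> MRResult:
    """Inverse-variance-weighted meta-analysis of per-SNP Wald ratios.

    Equals the slope of the zero-intercept weighted regression of outcome
    betas on exposure betas with weights 1/outcome_se^2.
    """
    s = instrument_set
    if (s.exposure_betas == 0).any():
        raise ValueError("exposure beta of zero gives an undefined Wald ratio")
    ratio = s.outcome_betas / s.exposure_betas
    w = (s.exposure_betas / s.outcome_ses) ** 2
    beta = float(np.sum(w * ratio) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    p = float(2 * stats.norm.sf(abs(beta / se)))
    return MRResult("ivw", beta, se, p, len(s))


def mr_egger(instrument_set: InstrumentSet) -> MRResult:
    """MR-Egger: weighted regression of outcome betas on exposure betas
    with a free intercept (directional-pleiotropy estimate).

    Instruments are first oriented so all exposure betas are
    non-negative; weights are 1/outcome_se^2; inference uses a
    t-distribution on n_instruments - 2 df.
    """
    s = instrument_set
    m = len(s)
    if m < 3:
        raise ValueError("MR-Egger needs at least 3 instruments")
    flip = np.sign(s.exposure_betas)
    flip[flip == 0] = 1.0
    bx = s.exposure_betas * flip
    by = s.outcome_betas * flip
    w = 1.0 / s.outcome_ses**2
    X = np.column_stack([np.ones(m), bx])
    WX = X * w[:, None]
    coef = np.linalg.solve(X.T @ WX, WX.T @ by)
    resid = by - X @ coef
    df = m - 2
    s2 = np.sum(w * resid**2) / df
    cov = s2 * np.linalg.inv(X.T @ WX)
    se_slope = float(np.sqrt(cov[1, 1]))
    se_int = float(np.sqrt(cov[0, 0]))
    p_slope = float(2 * stats.t.sf(abs(coef[1] / se_slope), df))
    p_int = float(2 * stats.t.sf(abs(coef[0] / se_int), df))
    return MRResult(
        "egger",
        float(coef[1]),
        se_slope,
        p_slope,
        m,
        egger_intercept=float(coef[0]),
        egger_intercept_se=se_int,
        egger_intercept_p=p_int,
    )


def ks_uniformity(p_values: np.ndarray) -> tuple[float, float]:
    """Two-sided one-sample KS test of p-values against Uniform(0, 1)."""
    res = stats.kstest(np.asarray(p_values, float), "uniform")
    return float(res.statistic), float(res.pvalue)


def funnel_data(instrument_set: InstrumentSet) -> pd.DataFrame:
    """MAF-corrected instrument strength |beta_exposure| * sqrt(2 maf (1-maf))
    against the per-SNP Wald ratio."""
    s = instrument_set
    strength = np.abs(s.exposure_betas) * np.sqrt(2 * s.maf * (1 - s.maf))
    ratio = s.outcome_betas / s.exposure_betas
    return pd.DataFrame(
        {"snp_id": s.snp_ids, "strength": strength, "wald_ratio": ratio}
    )


def mr_power_n(
    r2_exposure: float,
    beta_std: float,
    alpha: float = 0.05,
    power: float = 0.8,
) -> int:
    """Samples needed to detect the instrument-outcome association.

    With an instrument explaining ``r2_exposure`` of the exposure and a
    standardized causal effect ``beta_std``, the instrument-outcome
    variance explained is ``r2_exposure * beta_std**2`` and the normal
    approximation for a correlation test gives
    ``n = ceil((z_{1-alpha/2} + z_{power})^2 / R2_GY)``.
    """
    for name, v in (("r2_exposure", r2_exposure), ("beta_std", abs(beta_std)),
                    ("alpha", alpha), ("power", power)):
        if not (0 < v < 1):
            raise ValueError(f"{name} must be in (0, 1)")
    r2_gy = r2_exposure * beta_std**2
    z = stats.norm.ppf(1 - alpha / 2) + stats.norm.ppf(power)
    return int(np.ceil(z**2 / r2_gy))
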