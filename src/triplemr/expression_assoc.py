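"""Phenotype-associated gene discovery from RNA-seq counts.

RNA-seq count data are heteroscedastic, and remain so after the log-cpm
transform, so each observation receives a precision weight from the
fitted mean-variance trend (the voom approach) before per-gene weighted
least squares of log-cpm on the continuous ln-phenotype plus covariates.
Between-sample scaling uses the weighted trimmed mean of M-values (TMM).
Multiple testing over genes is controlled with Benjamini-Hochberg FDR.

No empirical-Bayes variance moderation is applied: plain WLS t-tests are
used, which keeps every contract closed-form testable and is
asymptotically equivalent at the cohort sizes this pipeline targets
(hundreds of samples).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .io import ExpressionData, SampleTable


def tmm_factors(
    counts: np.ndarray,
    ref_sample: int | None = None,
    trim_m: float = 0.3,
    trim_a: float = 0.05,
) -> np.ndarray:
    """Weighted trimmed-mean-of-M-values scaling factors, one per sample.

    The reference is the sample whose upper-quartile count fraction is
    closest to the mean upper quartile. For each sample, genes zero in
    either the sample or the reference are excluded; M-values (log2 ratio
    of library-size-scaled proportions) are doubly trimmed (``trim_m`` on
    M, ``trim_a`` on A, each side by rank) and averaged with delta-method
    precision weights. Factors are rescaled to geometric mean 1.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("sample with all-zero counts")
    if ref_sample is None:
        q75 = np.array([np.quantile(counts[:, j] / lib[j], 0.75) for j in range(counts.shape[1])])
        ref_sample = int(np.argmin(np.abs(q75 - q75.mean())))
    f = np.ones(counts.shape[1])
    yr, nr = counts[:, ref_sample], lib[ref_sample]
    for j in range(counts.shape[1]):
        if j == ref_sample:
            continue
        yk, nk = counts[:, j], lib[j]
        ok = (yk > 0) & (yr > 0)
        if ok.sum() == 0:
            continue
        pk, pr = yk[ok] / nk, yr[ok] / nr
        M = np.log2(pk / pr)
        A = 0.5 * np.log2(pk * pr)
        w = (nk - yk[ok]) / (nk * yk[ok]) + (nr - yr[ok]) / (nr * yr[ok])
        if np.max(np.abs(M)) < 1e-6:
            continue
        n = M.size
        lo_m = np.floor(n * trim_m) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * trim_a) + 1
        hi_a = n + 1 - lo_a
        rm = stats.rankdata(M)
        ra = stats.rankdata(A)
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if keep.sum() == 0 or w[keep].sum() == 0:
            continue
        f[j] = 2.0 ** (np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep]))
    return f / np.exp(np.mean(np.log(f)))


def logcpm(
    counts: np.ndarray, factors: np.ndarray | None = None, prior: float = 0.5
) -> np.ndarray:
    """log2 counts-per-million with a prior count and TMM-scaled library
    sizes: ``log2((count + prior) / (libsize*factor + 2*prior) * 1e6)``."""
    counts = np.asarray(counts, dtype=float)
    lib = counts.sum(axis=0)
    if factors is not None:
        lib = lib * np.asarray(factors, dtype=float)
    return np.log2((counts + prior) / (lib + 2 * prior) * 1e6)


def voom_weights(
    logcpm_mat: np.ndarray,
    design: np.ndarray,
    libsizes: np.ndarray,
    factors: np.ndarray | None = None,
    span: float = 0.5,
) -> np.ndarray:
    """Observation-level precision weights from the mean-variance trend.

    Gene-wise OLS of log-cpm on ``design`` yields residual SDs; a lowess
    curve of sqrt(SD) against mean log2-count is interpolated at each
    observation's fitted log2-count (clamped at the curve ends) and the
    weight is the interpolated value to the power -4.
    """
    Y = np.asarray(logcpm_mat, dtype=float)
    X = np.asarray(design, dtype=float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    if n <= p:
        raise ValueError("more design columns than samples")
    lib = np.asarray(libsizes, dtype=float)
    if factors is not None:
        lib = lib * np.asarray(factors, dtype=float)
    coef, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    fitted = (X @ coef).T  # genes x samples, log-cpm scale
    resid = Y - fitted
    sigma = np.sqrt((resid**2).sum(axis=1) / (n - p))
    # mean log2-count per gene and fitted log2-count per observation
    sx = Y.mean(axis=1) + np.mean(np.log2(lib + 1)) - np.log2(1e6)
    sy = np.sqrt(sigma)
    ok = sigma > 0
    curve = lowess(sy[ok], sx[ok], frac=span, return_sorted=True)
    cx, cy = curve[:, 0], curve[:, 1]
    fitted_logcount = fitted + np.log2(lib + 1)[None, :] - np.log2(1e6)
    interp = np.interp(fitted_logcount, cx, cy)  # clamps at curve range
    interp = np.maximum(interp, 1e-6)
    return interp**-4


def normalize_expression(
    ed: ExpressionData, design: np.ndarray, prior: float = 0.5, span: float = 0.5
) -> ExpressionData:
    """Convenience: fill ``norm_factors``, ``logcpm`` and ``weights``."""
    factors = tmm_factors(ed.counts)
    lcpm = logcpm(ed.counts, factors, prior=prior)
    w = voom_weights(lcpm, design, ed.library_sizes(), factors, span=span)
    return ExpressionData(
        ed.counts, ed.genes, ed.sample_ids, norm_factors=factors, logcpm=lcpm, weights=w
    )


def _check_collinearity(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by greedy QR
        bad = []
        cols: list[int] = []
        for j in range(X.shape[1]):
            trial = X[:, cols + [j]]
            if np.linalg.matrix_rank(trial) == len(cols):
                bad.append(names[j])
            else:
                cols.append(j)
        raise ValueError(f"collinear design columns: {bad}")


def fit_gene_assoc(
    ed: ExpressionData,
    sample_table: SampleTable,
    covariate_names: list[str] | None = None,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-gene weighted least squares of log-cpm on the ln-phenotype.

    The design is [intercept, ln-phenotype, covariates]; the reported
    coefficient is the phenotype's, tested with a t-distribution on
    ``n - p`` degrees of freedom, then BH-adjusted across genes.

    Returns a frame with columns ``gene_id, beta, se, ci95_lo, ci95_hi,
    t, p_nominal, p_adjusted, sign, significant`` sorted by ``p_nominal``.
    """
    if ed.logcpm is None or ed.weights is None:
        raise ValueError("expression must be normalized first (logcpm/weights)")
    covariate_names = (
        sample_table.covariates
        + sample_table.genotype_pcs
        + sample_table.expression_pcs
        if covariate_names is None
        else covariate_names
    )
    phen = sample_table.phenotype()
    X = np.column_stack(
        [
            np.ones(len(phen)),
            phen,
            sample_table.data[covariate_names].to_numpy(dtype=float),
        ]
    )
    _check_collinearity(X, ["intercept", sample_table.phenotype_col, *covariate_names])
    Y = ed.logcpm
    W = ed.weights
    n, p = X.shape
    # batched weighted normal equations: per gene, (X'WX) b = X'Wy
    XtWX = np.einsum("np,gn,nq->gpq", X, W, X, optimize=True)
    XtWy = np.einsum("np,gn,gn->gp", X, W, Y, optimize=True)
    beta_all = np.linalg.solve(XtWX, XtWy[..., None])[..., 0]
    fitted = beta_all @ X.T
    rss = np.einsum("gn,gn->g", W, (Y - fitted) ** 2)
    sigma2 = rss / (n - p)
    inv = np.linalg.inv(XtWX)
    se = np.sqrt(sigma2 * inv[:, 1, 1])
    beta = beta_all[:, 1]
    t = beta / se
    df = n - p
    p_nom = 2 * stats.t.sf(np.abs(t), df)
    reject, p_adj, *_ = multipletests(p_nom, alpha=fdr, method="fdr_bh")
    tcrit = stats.t.ppf(0.975, df)
    out = pd.DataFrame(
        {
            "gene_id": ed.genes["id"].values,
            "beta": beta,
            "se": se,
            "ci95_lo": beta - tcrit * se,
            "ci95_hi": beta + tcrit * se,
            "t": t,
            "p_nominal": p_nom,
            "p_adjusted": p_adj,
            "sign": np.where(beta >= 0, "+", "-"),
            "significant": reject,
        }
    )
    return out.sort_values("p_nominal", kind="stable").reset_index(drop=True)
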