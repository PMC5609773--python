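"""Quality control and covariate construction.

Variant filters (MAF >= 0.05, missingness <= 0.01), greedy sliding-window
LD pruning (r2 > 0.5, window 50 variants, step 5), GRM-based relatedness
removal (> 0.1 keeps one member per connected component), low-expression
filtering (cpm > 1 in >= 10 samples), principal components with a
deterministic sign convention, phenotype-guided selection of expression
PCs, and column-mean imputation.

All filters are idempotent and commute with sample/variant reordering
(outputs are identified by id, not index).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionData, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class QCReport:
    variants_removed_maf: int = 0
    variants_removed_missing: int = 0
    samples_removed_related: list[str] = field(default_factory=list)
    genes_removed_lowexpr: int = 0
    pcs_genotype: np.ndarray | None = None
    pcs_expression: np.ndarray | None = None
    expression_pcs_selected: list[int] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "variants_removed_maf": self.variants_removed_maf,
            "variants_removed_missing": self.variants_removed_missing,
            "samples_removed_related": list(self.samples_removed_related),
            "genes_removed_lowexpr": self.genes_removed_lowexpr,
            "expression_pcs_selected": list(self.expression_pcs_selected),
        }


def filter_variants(
    gm: GenotypeMatrix,
    maf_min: float = 0.05,
    missing_max: float = 0.01,
    report: QCReport | None = None,
) -> GenotypeMatrix:
    """Drop variants with MAF < ``maf_min`` (non-missing denominator) or
    missing fraction > ``missing_max``."""
    maf = gm.maf()
    miss = gm.missing_rate()
    keep_maf = maf >= maf_min
    keep_miss = miss <= missing_max
    keep = keep_maf & keep_miss
    if report is not None:
        report.variants_removed_maf = int((~keep_maf).sum())
        report.variants_removed_missing = int((keep_maf & ~keep_miss).sum())
    if not keep.any():
        raise ValueError("no variants survive QC")
    return gm.subset_variants(np.flatnonzero(keep))


def _pairwise_r2(dos: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between dosage columns, pairwise-complete."""
    m = dos.shape[1]
    if np.isfinite(dos).all():
        with np.errstate(invalid="ignore"):
            r = np.corrcoef(dos, rowvar=False)
        return np.nan_to_num(r) ** 2
    r2 = np.zeros((m, m))
    for a in range(m):
        for b in range(a + 1, m):
            ok = np.isfinite(dos[:, a]) & np.isfinite(dos[:, b])
            if ok.sum() > 2 and dos[ok, a].std() > 0 and dos[ok, b].std() > 0:
                r2[a, b] = r2[b, a] = np.corrcoef(dos[ok, a], dos[ok, b])[0, 1] ** 2
    return r2


def ld_prune(
    gm: GenotypeMatrix,
    window: int = 50,
    step: int = 5,
    r2_max: float = 0.5,
) -> np.ndarray:
    """Greedy within-window LD pruning; returns retained variant indices.

    Within each window of ``window`` consecutive position-sorted variants,
    while any retained pair exceeds ``r2_max`` the member of the worst
    pair with the smaller MAF is dropped (tie: the later position); the
    window then slides by ``step`` variants.
    """
    order_ok = (
        gm.variants.groupby("chrom", sort=False)["pos"].apply(lambda s: s.is_monotonic_increasing).all()
    )
    if not order_ok:
        raise ValueError("variants must be position-sorted within chromosome")
    maf = gm.maf()
    m = gm.n_variants
    keep = np.ones(m, dtype=bool)
    chrom = gm.variants["chrom"].to_numpy()
    for start in range(0, max(m - 1, 1), step):
        idx = np.arange(start, min(start + window, m))
        idx = idx[keep[idx]]
        idx = idx[chrom[idx] == chrom[idx[0]]] if idx.size else idx
        if idx.size < 2:
            continue
        r2 = _pairwise_r2(gm.dosages[:, idx])
        np.fill_diagonal(r2, 0.0)
        active = np.ones(idx.size, dtype=bool)
        while True:
            sub = np.where(active)[0]
            if sub.size < 2:
                break
            block = r2[np.ix_(sub, sub)]
            worst = np.unravel_index(np.argmax(block), block.shape)
            if block[worst] <= r2_max:
                break
            a, b = sub[worst[0]], sub[worst[1]]
            ia, ib = idx[a], idx[b]
            if maf[ia] < maf[ib]:
                drop = a
            elif maf[ib] < maf[ia]:
                drop = b
            else:  # tie: drop the later position
                drop = a if gm.variants.loc[ia, "pos"] > gm.variants.loc[ib, "pos"] else b
            active[drop] = False
            keep[idx[drop]] = False
    return np.flatnonzero(keep)


def relatedness_matrix(gm: GenotypeMatrix) -> np.ndarray:
    """GRM: mean over variants of standardized-dosage products; missing
    dosages are mean-imputed (contribute zero after centering)."""
    dos = gm.dosages.copy()
    mean = np.nanmean(dos, axis=0)
    sd = np.nanstd(dos, axis=0)
    ok = sd > 0
    z = (dos[:, ok] - mean[ok]) / sd[ok]
    z = np.nan_to_num(z)
    return z @ z.T / ok.sum()


def relatedness_filter(
    gm_pruned: GenotypeMatrix,
    threshold: float = 0.1,
    report: QCReport | None = None,
    min_variants: int | None = None,
) -> list[str]:
    """Sample ids to drop so no retained pair has relatedness > threshold.

    Connected components of the above-threshold graph are formed; all but
    one member per component are dropped (kept: highest genotype call
    rate, tie broken by sample order).

    The GRM off-diagonal has sampling SD ~ 1/sqrt(m) over m variants, so
    the threshold is only meaningful when m >> 1/threshold^2. Unless
    overridden by ``min_variants``, the filter requires the sampling SD
    to be below threshold/3 (m >= 9/threshold^2) and otherwise skips
    with a warning rather than chain unrelated samples into spurious
    components.
    """
    if min_variants is None:
        min_variants = int(np.ceil(9.0 / threshold**2))
    if gm_pruned.n_variants < min_variants:
        logger.warning(
            "relatedness filter skipped: %d variants < %d needed for a reliable "
            "GRM at threshold %.3g",
            gm_pruned.n_variants, min_variants, threshold,
        )
        return []
    grm = relatedness_matrix(gm_pruned)
    n = grm.shape[0]
    adj = (grm > threshold).astype(int)
    np.fill_diagonal(adj, 0)
    # union-find over the above-threshold graph
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in zip(*np.nonzero(np.triu(adj))):
        ra, rb = find(int(a)), find(int(b))
        if ra != rb:
            parent[rb] = ra
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    call_rate = np.mean(np.isfinite(gm_pruned.dosages), axis=1)
    drop: list[str] = []
    for members in comps.values():
        if len(members) < 2:
            continue
        best = max(members, key=lambda i: (call_rate[i], -i))
        drop.extend(gm_pruned.sample_ids[i] for i in members if i != best)
    drop = sorted(drop, key=gm_pruned.sample_ids.index)
    if report is not None:
        report.samples_removed_related = drop
    return drop


def low_expression_filter(
    ed: ExpressionData,
    cpm_min: float = 1.0,
    min_samples: int = 10,
    report: QCReport | None = None,
) -> ExpressionData:
    """Keep genes with cpm > ``cpm_min`` in at least ``min_samples``
    samples (raw library sizes; no between-sample normalization here)."""
    lib = ed.library_sizes()
    cpm = ed.counts / lib * 1e6
    keep = (cpm > cpm_min).sum(axis=1) >= min_samples
    if report is not None:
        report.genes_removed_lowexpr = int((~keep).sum())
    if not keep.any():
        raise ValueError("all genes removed by low-expression filter")
    return ed.subset_genes(np.flatnonzero(keep))


def compute_pcs(
    matrix: np.ndarray,
    k: int,
    center: bool = True,
    scale: bool = False,
) -> np.ndarray:
    """Top-k principal component scores of a samples x features matrix.

    Missing entries are mean-imputed before the SVD. The sign of each
    component is fixed by making its largest-magnitude loading positive,
    so pipelines are reproducible across runs.
    """
    X = np.asarray(matrix, dtype=float).copy()
    mean = np.nanmean(X, axis=0)
    inds = np.where(~np.isfinite(X))
    X[inds] = np.take(mean, inds[1])
    if center:
        X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0)
        X = X / np.where(sd > 0, sd, 1.0)
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    if k > rank:
        raise ValueError(f"k={k} exceeds matrix rank {rank}")
    signs = np.sign(vt[np.arange(k), np.argmax(np.abs(vt[:k]), axis=1)])
    signs[signs == 0] = 1.0
    return (u[:, :k] * s[:k]) * signs


def select_expression_pcs(
    pcs: np.ndarray,
    phenotype: np.ndarray,
    alpha: float = 0.05,
    k_max: int = 10,
) -> list[int]:
    """Prefix of PCs (1-based indices) preceding the first PC associated
    with the phenotype at level ``alpha`` (simple-regression t-test).

    Returns an empty list with a warning when PC1 is already associated.
    """
    k = min(pcs.shape[1], k_max)
    selected: list[int] = []
    for j in range(k):
        res = stats.linregress(pcs[:, j], phenotype)
        if res.pvalue < alpha:
            if j == 0:
                logger.warning(
                    "leading expression PC is already phenotype-associated; selecting none"
                )
            return selected
        selected.append(j + 1)
    return selected


def mean_impute(
    table: pd.DataFrame, columns: list[str] | None = None
) -> pd.DataFrame:
    """Replace missing entries by the column mean over observed entries."""
    out = table.copy()
    for col in columns or table.columns:
        s = out[col]
        n_missing = int(s.isna().sum())
        if n_missing == len(s):
            raise ValueError(f"column {col!r} entirely missing")
        if n_missing:
            out[col] = s.fillna(s.mean())
            logger.info("imputed %d value(s) in column %s", n_missing, col)
    return out
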