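"""End-to-end orchestration: QC -> association -> cis-eQTL -> triplets -> MR.

A triplet becomes a final causal call only when it clears all three
gates: a causal-vs-colliding AIC gap of at least 10, a passing
partial-correlation (d-separation) check, and a significant Mendelian-
randomization estimate. The MR gate accepts either individual-level TSLS
(when instrument genotypes are available in the cohort) or, for causal
candidates, a significant SNP-phenotype association in the published
summary statistics.

`run_study` operates on in-memory containers and is the unit the tests
exercise; `run_pipeline` wraps it with config validation, file I/O and a
machine-readable report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import (
    ExpressionData,
    GenotypeMatrix,
    SampleTable,
    SummaryStatsTable,
    read_counts,
    read_genotypes,
    read_sample_table,
    read_summary_stats,
    write_results,
)
from . import cis_eqtl as ce
from . import expression_assoc as ea
from . import mr as mrmod
from . import preprocess as pp
from . import triplets as tc

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    def __init__(self, errors: list[str]):
        super().__init__("; ".join(errors))
        self.errors = errors


DEFAULTS: dict = {
    "seed": 0,
    "maf_min": 0.05,
    "missing_max": 0.01,
    "ld_window": 50,
    "ld_step": 5,
    "ld_r2_max": 0.5,
    "relatedness_threshold": 0.1,
    "cpm_min": 1.0,
    "min_samples_expressed": 10,
    "n_genotype_pcs": 4,
    "expression_pc_kmax": 10,
    "cis_window": 250_000,
    "fdr": 0.05,
    "n_perm": 10_000,
    "alpha": 0.05,
    "delta_aic_moderate": 2.0,
    "delta_aic_strong": 10.0,
}

_PATH_KEYS = ("genotypes", "counts", "gene_annotation", "samples", "summary_stats")


def validate_config(source: str | Path | dict) -> dict:
    """Fill defaults and validate a pipeline config (YAML path or dict).

    Unknown keys, missing input paths and out-of-range values are
    collected into a single :class:`ConfigError`. Idempotent:
    ``validate_config(validate_config(c)) == validate_config(c)``.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            cfg = yaml.safe_load(fh) or {}
    else:
        cfg = dict(source)
    errors: list[str] = []
    known = set(DEFAULTS) | set(_PATH_KEYS) | {"out_dir"}
    for key in cfg:
        if key not in known:
            errors.append(f"unknown config key {key!r}")
    norm = {**DEFAULTS, **{k: v for k, v in cfg.items() if k in known}}
    for key in ("maf_min", "missing_max", "fdr", "alpha"):
        if not (0 < float(norm[key]) < 1):
            errors.append(f"{key} must be in (0, 1)")
    for key in ("cis_window", "ld_window", "ld_step", "n_perm", "n_genotype_pcs"):
        if int(norm[key]) <= 0:
            errors.append(f"{key} must be positive")
    for key in _PATH_KEYS:
        if key in norm and norm[key] is not None and not Path(norm[key]).exists():
            errors.append(f"input path for {key!r} does not exist: {norm[key]}")
    if errors:
        raise ConfigError(errors)
    return norm


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


@dataclass
class StudyResult:
    """Stage tables, gate funnel counts and final causal calls."""

    stage_counts: dict = field(default_factory=dict)
    assoc: pd.DataFrame | None = None
    eqtl_hits: pd.DataFrame | None = None
    triplet_table: pd.DataFrame | None = None
    mr_table: pd.DataFrame | None = None
    final_calls: list[dict] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def report(self) -> dict:
        return {
            "stage_counts": self.stage_counts,
            "final_calls": self.final_calls,
            "provenance": self.provenance,
        }


def _covariate_matrix(st: SampleTable, include_expression_pcs: bool = True) -> np.ndarray:
    cols = list(st.covariates) + list(st.genotype_pcs)
    if include_expression_pcs:
        cols += list(st.expression_pcs)
    return st.data[cols].to_numpy(dtype=float)


def run_study(
    gm: GenotypeMatrix,
    ed: ExpressionData,
    st: SampleTable,
    sumstats: SummaryStatsTable | None = None,
    params: dict | None = None,
    seed: int | None = None,
) -> StudyResult:
    """Execute the full analysis on in-memory data."""
    cfg = {**DEFAULTS, **(params or {})}
    if seed is not None:
        cfg["seed"] = seed
    rng = np.random.default_rng(cfg["seed"])
    res = StudyResult()
    counts = res.stage_counts
    report = pp.QCReport()

    # ---- stage 1: QC ------------------------------------------------------
    counts["variants_in"] = gm.n_variants
    counts["samples_in"] = gm.n_samples
    counts["genes_in"] = ed.n_genes
    gm = pp.filter_variants(gm, cfg["maf_min"], cfg["missing_max"], report)
    pruned_idx = pp.ld_prune(gm, cfg["ld_window"], cfg["ld_step"], cfg["ld_r2_max"])
    gm_pruned = gm.subset_variants(pruned_idx)
    drop = pp.relatedness_filter(gm_pruned, cfg["relatedness_threshold"], report)
    if drop:
        keep_ids = [s for s in gm.sample_ids if s not in set(drop)]
        gm = gm.subset_samples(keep_ids)
        gm_pruned = gm_pruned.subset_samples(keep_ids)
        ed = ed.subset_samples(keep_ids)
        st = st.aligned_to(keep_ids)
    ed = pp.low_expression_filter(
        ed, cfg["cpm_min"], cfg["min_samples_expressed"], report
    )
    st = SampleTable(
        pp.mean_impute(st.data),
        phenotype_col=st.phenotype_col,
        covariates=st.covariates,
    )
    k_g = min(cfg["n_genotype_pcs"], gm_pruned.n_samples - 1, gm_pruned.n_variants)
    gpcs = pp.compute_pcs(gm_pruned.dosages, k=k_g)
    report.pcs_genotype = gpcs
    data = st.data.copy()
    gpc_names = [f"geno_pc{i+1}" for i in range(k_g)]
    data[gpc_names] = gpcs
    counts["variants_qc"] = gm.n_variants
    counts["samples_qc"] = gm.n_samples
    counts["genes_expressed"] = ed.n_genes

    # ---- stage 2: normalization and expression PCs ------------------------
    factors = ea.tmm_factors(ed.counts)
    lcpm = ea.logcpm(ed.counts, factors)
    n_epc = min(cfg["expression_pc_kmax"], ed.n_samples - 1, ed.n_genes)
    epcs = pp.compute_pcs(lcpm.T, k=n_epc)
    report.pcs_expression = epcs
    sel = pp.select_expression_pcs(
        epcs, st.phenotype(), alpha=cfg["alpha"], k_max=cfg["expression_pc_kmax"]
    )
    report.expression_pcs_selected = sel
    epc_names = [f"expr_pc{i}" for i in sel]
    for i, name in zip(sel, epc_names):
        data[name] = epcs[:, i - 1]
    st = SampleTable(
        data,
        phenotype_col=st.phenotype_col,
        covariates=st.covariates,
        genotype_pcs=gpc_names,
        expression_pcs=epc_names,
    )
    design = np.column_stack(
        [np.ones(ed.n_samples), st.phenotype(), _covariate_matrix(st)]
    )
    weights = ea.voom_weights(lcpm, design, ed.library_sizes(), factors)
    ed = ExpressionData(
        ed.counts, ed.genes, ed.sample_ids,
        norm_factors=factors, logcpm=lcpm, weights=weights,
    )
    res.provenance["qc"] = report.summary()

    # ---- stage 3: phenotype-expression association ------------------------
    assoc = ea.fit_gene_assoc(ed, st, fdr=cfg["fdr"])
    res.assoc = assoc
    sig_genes = assoc.loc[assoc["significant"], "gene_id"].tolist()
    counts["genes_associated"] = len(sig_genes)
    if not sig_genes:
        res.provenance.update(_provenance(cfg))
        return res

    # ---- stage 4: cis-eQTL with permutation calibration -------------------
    cov_full = _covariate_matrix(st, include_expression_pcs=True)
    sig_gene_tab = ed.genes[ed.genes["id"].isin(sig_genes)]
    pairs = ce.cis_pairs(sig_gene_tab, gm.variants, window=cfg["cis_window"])
    counts["cis_pairs"] = len(pairs)
    scan = ce.eqtl_scan(pairs, ed, gm, cov_full)
    n_genes_tested = len(sig_genes)
    hit_frames = []
    independent: dict[str, list[str]] = {}
    for gene_id, sub in scan.groupby("gene_id", sort=False):
        snps = sub["snp_id"].tolist()
        minp = ce.permutation_null(
            gene_id, snps, ed, gm, cov_full,
            n_perm=cfg["n_perm"], seed=int(rng.integers(2**31 - 1)),
        )
        fit = ce.gumbel_fit(minp)
        sub = sub.copy()
        sub["p_perm"] = ce.p_perm(fit, sub["p_nominal"].to_numpy())
        sub = ce.gene_bonferroni(sub, n_genes_tested, alpha=cfg["alpha"])
        hit_frames.append(sub)
        sig_snps = sub.loc[sub["significant"]]
        if len(sig_snps):
            order = sig_snps.sort_values("p_nominal", kind="stable")["snp_id"].tolist()
            independent[gene_id] = ce.stepwise_independent(
                gene_id, order, ed, gm, cov_full,
                p_enter=cfg["alpha"] / n_genes_tested,
            )
    hits = pd.concat(hit_frames, ignore_index=True) if hit_frames else pd.DataFrame()
    res.eqtl_hits = hits
    counts["eqtl_hits"] = int(hits["significant"].sum()) if len(hits) else 0
    counts["genes_with_eqtl"] = len(independent)
    counts["independent_eqtls"] = sum(len(v) for v in independent.values())

    # ---- stage 5: triplet model selection ---------------------------------
    X_expr = np.column_stack([np.ones(ed.n_samples), cov_full])
    cov_phen = _covariate_matrix(st, include_expression_pcs=False)
    X_phen = np.column_stack([np.ones(ed.n_samples), cov_phen])
    c_resid = tc.residualize(st.phenotype(), X_phen)
    trip_rows, candidates = [], []
    snp_col = {s: j for j, s in enumerate(gm.variants["id"])}
    for gene_id, snps in independent.items():
        e_resid = tc.residualize(ed.logcpm[list(ed.genes["id"]).index(gene_id)], X_expr)
        for snp_id in snps:
            g = gm.dosages[:, snp_col[snp_id]]
            ok = np.isfinite(g)
            fit = tc.fit_triplet(
                g[ok], e_resid[ok], c_resid[ok],
                gene_id=gene_id, snp_id=snp_id, alpha=cfg["alpha"],
            )
            row = {
                "gene_id": gene_id,
                "snp_id": snp_id,
                **{f"aic_{m}": fit.aic[m] for m in tc.MODELS},
                "best_model": fit.best_model,
                "direction": fit.direction,
                "delta_aic": fit.delta_aic,
                "evidence_class": fit.evidence_class,
                "pc_pass": fit.pc_verdict.get("pass"),
                "pc_p_marginal": fit.pc_verdict.get("p_marginal"),
                "pc_p_conditional": fit.pc_verdict.get("p_conditional"),
            }
            trip_rows.append(row)
            if fit.delta_aic >= cfg["delta_aic_strong"] and fit.pc_verdict.get("pass"):
                candidates.append(fit)
    trip = pd.DataFrame(trip_rows)
    res.triplet_table = trip
    counts["triplets"] = len(trip)
    if len(trip):
        counts["triplets_informative"] = int(
            (trip["delta_aic"] >= cfg["delta_aic_moderate"]).sum()
        )
        counts["triplets_strong"] = int(
            (trip["delta_aic"] >= cfg["delta_aic_strong"]).sum()
        )
    counts["candidates"] = len(candidates)

    # ---- stage 6: Mendelian randomization gate ----------------------------
    mr_rows = []
    for fit in candidates:
        verdict: dict = {
            "gene_id": fit.gene_id,
            "snp_id": fit.snp_id,
            "best_model": fit.best_model,
            "direction": fit.direction,
            "delta_aic": fit.delta_aic,
        }
        if sumstats is None:
            verdict.update({"mr_method": "none", "mr_pass": False})
            mr_rows.append(verdict)
            continue
        if fit.direction == "colliding":
            e_resid = tc.residualize(
                ed.logcpm[list(ed.genes["id"]).index(fit.gene_id)], X_expr
            )
            try:
                G, *_ = mrmod.align_instruments(gm, sumstats)
                Gi = G.copy()
                col_mean = np.nanmean(Gi, axis=0)
                inds = np.where(~np.isfinite(Gi))
                Gi[inds] = np.take(col_mean, inds[1])
                import warnings

                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    mrres = mrmod.tsls(c_resid, e_resid, Gi)
                verdict.update(
                    {
                        "mr_method": mrres.method,
                        "mr_beta": mrres.beta,
                        "mr_se": mrres.se,
                        "mr_p": mrres.p,
                        "mr_pass": bool(mrres.p < cfg["alpha"]),
                    }
                )
            except ValueError as exc:
                verdict.update({"mr_method": "tsls_failed", "mr_error": str(exc), "mr_pass": False})
        else:  # causal: the eQTL must associate with the phenotype in the GWAS
            row = sumstats.data[sumstats.data["snp_id"] == fit.snp_id]
            if len(row):
                p = float(row["p"].iloc[0])
                verdict.update(
                    {"mr_method": "gwas_lookup", "mr_p": p, "mr_pass": bool(p < cfg["alpha"])}
                )
            else:
                verdict.update({"mr_method": "gwas_lookup", "mr_p": None, "mr_pass": False})
        mr_rows.append(verdict)
    res.mr_table = pd.DataFrame(mr_rows)
    res.final_calls = [r for r in mr_rows if r.get("mr_pass")]
    counts["final_calls"] = len(res.final_calls)
    res.provenance.update(_provenance(cfg))
    return res


def _provenance(cfg: dict) -> dict:
    return {
        "config": {k: cfg[k] for k in sorted(DEFAULTS)},
        "config_hash": config_hash({k: cfg[k] for k in sorted(DEFAULTS)}),
        "seed": cfg["seed"],
        "version": __version__,
    }


def run_pipeline(config: str | Path | dict) -> StudyResult:
    """Validate config, read inputs, run the study and persist outputs."""
    cfg = validate_config(config)
    missing = [k for k in ("genotypes", "counts", "gene_annotation", "samples") if not cfg.get(k)]
    if missing:
        raise ConfigError([f"missing required input path {k!r}" for k in missing])
    gm = read_genotypes(cfg["genotypes"])
    ed = read_counts(cfg["counts"], cfg["gene_annotation"])
    st = read_sample_table(cfg["samples"])
    # every non-phenotype column in the sample table is a covariate
    covars = [c for c in st.data.columns if c not in (st.phenotype_col, "phenotype_raw")]
    st = SampleTable(st.data, phenotype_col=st.phenotype_col, covariates=covars)
    common = [s for s in gm.sample_ids if s in set(ed.sample_ids) and s in set(st.sample_ids)]
    gm = gm.subset_samples(common)
    ed = ed.subset_samples(common)
    st = st.aligned_to(common)
    sumstats = (
        read_summary_stats(cfg["summary_stats"]) if cfg.get("summary_stats") else None
    )
    res = run_study(gm, ed, st, sumstats, params=cfg)
    out_dir = Path(cfg.get("out_dir") or "triplemr_out")
    tables = {
        name: tab
        for name, tab in (
            ("association", res.assoc),
            ("eqtl_hits", res.eqtl_hits),
            ("triplets", res.triplet_table),
            ("mr_results", res.mr_table),
        )
        if tab is not None and len(tab)
    }
    write_results(tables, out_dir)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(res.report(), fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")
    logger.info("pipeline finished: %s", res.stage_counts)
    return res


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
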