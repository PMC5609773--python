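"""Readers, writers and validated containers for every external format the pipeline touches.

Containers
----------
:class:`GenotypeMatrix`
    Samples x variants minor-allele dosages with variant metadata.
:class:`ExpressionData`
    Genes x samples raw counts plus derived normalized log-cpm and
    observation-level precision weights.
:class:`SampleTable`
    Per-sample phenotype (natural-log scale), covariates and principal
    components, row-aligned to the matrices it is joined to.
:class:`SummaryStatsTable`
    GWAS summary statistics used to build genetic instruments.

All genomic coordinates are 1-based inclusive (VCF/GFF convention).
Dosage values are restricted to {0, 1, 2, missing}; the analysis model is
strictly biallelic additive, so multi-allelic sites are rejected rather
than split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

logger = logging.getLogger(__name__)

VARIANT_COLUMNS = ["id", "chrom", "pos", "ref", "alt"]
GENE_COLUMNS = ["id", "chrom", "start", "end"]
SUMSTATS_COLUMNS = ["snp_id", "effect_allele", "other_allele", "beta", "se", "p", "eaf"]


class FormatError(ValueError):
    """A file failed to parse under its declared standard."""


# ---------------------------------------------------------------------------
# GenotypeMatrix
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix oriented to the minor allele.

    Parameters
    ----------
    dosages
        Float array of shape ``(n_samples, n_variants)`` with values in
        ``{0.0, 1.0, 2.0}`` and ``NaN`` for missing calls.
    variants
        Frame with columns ``id, chrom, pos, ref, alt`` (pos 1-based).
    sample_ids
        Ordered sample identifiers, one per dosage row.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.variants = self.variants.reset_index(drop=True)
        self.sample_ids = list(self.sample_ids)
        self.validate()

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        n, m = self.dosages.shape
        if n != len(self.sample_ids):
            raise ValueError("dosage rows do not match sample_ids")
        if m != len(self.variants):
            raise ValueError("dosage columns do not match variant table")
        ids = self.variants["id"]
        if ids.duplicated().any():
            dups = ids[ids.duplicated()].tolist()
            raise ValueError(f"duplicate variant ids: {dups}")
        if (self.variants["pos"] < 1).any():
            raise ValueError("variant positions must be 1-based positive")
        vals = self.dosages[np.isfinite(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be in {0,1,2} or missing")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def maf(self) -> np.ndarray:
        """Per-variant minor-allele frequency over non-missing calls."""
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def missing_rate(self) -> np.ndarray:
        return np.mean(~np.isfinite(self.dosages), axis=0)

    def orient_minor(self) -> "GenotypeMatrix":
        """Reflect dosages (d -> 2-d) and swap alleles where the counted
        allele frequency exceeds 0.5.

        Idempotent: re-orienting an oriented matrix changes nothing.
        """
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(self.dosages, axis=0) / 2.0
        flip = freq > 0.5
        if not flip.any():
            return self
        dos = self.dosages.copy()
        dos[:, flip] = 2.0 - dos[:, flip]
        var = self.variants.copy()
        ref = var.loc[flip, "ref"].copy()
        var.loc[flip, "ref"] = var.loc[flip, "alt"].values
        var.loc[flip, "alt"] = ref.values
        return GenotypeMatrix(dos, var, self.sample_ids)

    def subset_variants(self, index: np.ndarray | list[int]) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.dosages[:, index], self.variants.iloc[index], self.sample_ids
        )

    def subset_samples(self, keep_ids: list[str]) -> "GenotypeMatrix":
        pos = [self.sample_ids.index(s) for s in keep_ids]
        return GenotypeMatrix(self.dosages[pos, :], self.variants, keep_ids)


def read_genotypes(path: str | Path, format: str = "auto") -> GenotypeMatrix:
    """Read genotypes from a VCF (GT field) or a dosage TSV.

    The result is always minor-allele oriented: sites where the counted
    (alt) allele frequency exceeds 0.5 have their dosages reflected
    ``2 - d`` and allele columns swapped.
    """
    path = Path(path)
    if format == "auto":
        format = "vcf" if path.suffix in {".vcf", ".gz"} or path.name.endswith(".vcf.gz") else "dosage_tsv"
    if format == "vcf":
        gm = _read_vcf(path)
    elif format == "dosage_tsv":
        gm = _read_dosage_tsv(path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")
    return gm.orient_minor()


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    rows: list[np.ndarray] = []
    meta: list[tuple] = []
    # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
    code = np.array([0.0, 1.0, np.nan, 2.0])
    for v in vcf:
        if len(v.ALT) != 1:
            raise FormatError(f"multi-allelic site not supported: {v.ID or v.POS}")
        rows.append(code[v.gt_types])
        meta.append((v.ID or f"{v.CHROM}:{v.POS}", str(v.CHROM), v.POS, v.REF, v.ALT[0]))
    vcf.close()
    if not rows:
        raise FormatError(f"no variant records in {path}")
    variants = pd.DataFrame(meta, columns=VARIANT_COLUMNS)
    return GenotypeMatrix(np.vstack(rows).T, variants, sample_ids)


def _read_dosage_tsv(path: Path) -> GenotypeMatrix:
    """Dosage dialect: variants as rows; columns id, chrom, pos, ref, alt,
    then one column per sample; ``NA`` for missing."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing_cols = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"dosage TSV missing columns {missing_cols}")
    sample_ids = [c for c in df.columns if c not in VARIANT_COLUMNS]
    if not sample_ids:
        raise FormatError("dosage TSV has no sample columns")
    for col in ("ref", "alt"):
        bad = df[col].astype(str).str.contains(",")
        if bad.any():
            raise FormatError(
                f"multi-allelic variant(s): {df.loc[bad, 'id'].tolist()}"
            )
    dos = df[sample_ids].to_numpy(dtype=float).T
    return GenotypeMatrix(dos, df[VARIANT_COLUMNS], sample_ids)


def write_dosage_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    cols = {
        s: ["NA" if not np.isfinite(v) else str(int(v)) for v in gm.dosages[j, :]]
        for j, s in enumerate(gm.sample_ids)
    }
    out = pd.concat(
        [gm.variants, pd.DataFrame(cols, index=gm.variants.index)], axis=1
    )
    out.to_csv(path, sep="\t", index=False)


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with GT genotypes (missing -> ./.)."""
    gt_of = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = pd.unique(gm.variants["chrom"])
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        order = gm.variants.sort_values(["chrom", "pos"], kind="stable").index
        for i in order:
            v = gm.variants.loc[i]
            calls = [
                gt_of.get(d, "./.") if np.isfinite(d) else "./."
                for d in gm.dosages[:, i]
            ]
            fh.write(
                f"{v['chrom']}\t{v['pos']}\t{v['id']}\t{v['ref']}\t{v['alt']}"
                f"\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n"
            )


# ---------------------------------------------------------------------------
# ExpressionData
# ---------------------------------------------------------------------------


@dataclass
class ExpressionData:
    """Genes x samples raw counts with optional derived quantities.

    ``norm_factors`` (geometric mean 1 after normalization), ``logcpm`` and
    ``weights`` are filled in by the normalization stage and stay aligned
    with ``counts``.
    """

    counts: np.ndarray
    genes: pd.DataFrame
    sample_ids: list[str]
    norm_factors: np.ndarray | None = None
    logcpm: np.ndarray | None = None
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.genes = self.genes.reset_index(drop=True)
        self.sample_ids = list(self.sample_ids)
        self.validate()

    def validate(self) -> None:
        g, n = self.counts.shape
        if g != len(self.genes):
            raise ValueError("count rows do not match gene table")
        if n != len(self.sample_ids):
            raise ValueError("count columns do not match sample_ids")
        if self.genes["id"].duplicated().any():
            raise ValueError(
                f"duplicated gene id: {self.genes['id'][self.genes['id'].duplicated()].tolist()}"
            )
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integral")
            self.counts = np.round(self.counts).astype(np.int64)
        if (self.genes["start"] > self.genes["end"]).any():
            raise ValueError("gene start must be <= end")
        if self.norm_factors is not None and (np.asarray(self.norm_factors) <= 0).any():
            raise ValueError("norm factors must be positive")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0).astype(float)

    def subset_genes(self, index: np.ndarray | list[int]) -> "ExpressionData":
        index = np.asarray(index)
        return ExpressionData(
            self.counts[index, :],
            self.genes.iloc[index],
            self.sample_ids,
            norm_factors=self.norm_factors,
            logcpm=None if self.logcpm is None else self.logcpm[index, :],
            weights=None if self.weights is None else self.weights[index, :],
        )

    def subset_samples(self, keep_ids: list[str]) -> "ExpressionData":
        pos = [self.sample_ids.index(s) for s in keep_ids]
        return ExpressionData(
            self.counts[:, pos],
            self.genes,
            keep_ids,
            norm_factors=None if self.norm_factors is None else np.asarray(self.norm_factors)[pos],
            logcpm=None if self.logcpm is None else self.logcpm[:, pos],
            weights=None if self.weights is None else self.weights[:, pos],
        )


def read_counts(path: str | Path, gene_annot_path: str | Path) -> ExpressionData:
    """Read a gene x sample count matrix (TSV or MatrixMarket triplet).

    For MatrixMarket input, gene and sample names are read from sibling
    files ``<stem>.genes.txt`` and ``<stem>.samples.txt``. Genes absent
    from the coordinate annotation are dropped with a logged count;
    duplicated gene ids and non-integer counts are errors.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        raw = mmread(path)
        mat = np.asarray(raw.toarray() if hasattr(raw, "toarray") else raw)
        gene_ids = path.with_suffix(".genes.txt").read_text().split()
        sample_ids = path.with_suffix(".samples.txt").read_text().split()
        counts = pd.DataFrame(mat, index=gene_ids, columns=sample_ids)
    else:
        counts = pd.read_csv(path, sep="\t", index_col=0)
    if counts.index.duplicated().any():
        raise FormatError(
            f"duplicated gene id in {path}: {counts.index[counts.index.duplicated()].tolist()}"
        )
    vals = counts.to_numpy()
    if not np.allclose(vals, np.round(vals)):
        raise FormatError(f"non-integer count in {path}")
    annot = pd.read_csv(gene_annot_path, sep="\t", dtype={"chrom": str})
    missing_cols = [c for c in GENE_COLUMNS if c not in annot.columns]
    if missing_cols:
        raise FormatError(f"gene annotation missing columns {missing_cols}")
    annot = annot.set_index("id")
    have = counts.index.isin(annot.index)
    n_dropped = int((~have).sum())
    if n_dropped:
        logger.warning("dropping %d gene(s) lacking coordinates", n_dropped)
    counts = counts.loc[have]
    genes = annot.loc[counts.index]
    genes.index.name = "id"
    genes = genes.reset_index()[GENE_COLUMNS]
    return ExpressionData(
        counts.to_numpy(dtype=np.int64), genes, list(counts.columns)
    )


def write_counts_tsv(ed: ExpressionData, path: str | Path) -> None:
    pd.DataFrame(
        ed.counts, index=ed.genes["id"].values, columns=ed.sample_ids
    ).to_csv(path, sep="\t", index_label="gene_id")


def write_counts_mtx(ed: ExpressionData, path: str | Path) -> None:
    path = Path(path)
    mmwrite(str(path), coo_matrix(ed.counts))
    path.with_suffix(".genes.txt").write_text("\n".join(ed.genes["id"]) + "\n")
    path.with_suffix(".samples.txt").write_text("\n".join(ed.sample_ids) + "\n")


def write_gene_annot(ed: ExpressionData, path: str | Path) -> None:
    ed.genes[GENE_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# SampleTable
# ---------------------------------------------------------------------------


@dataclass
class SampleTable:
    """Per-sample phenotype, covariates and principal components.

    ``data`` is indexed by sample id; ``phenotype_col`` holds the natural
    log of the raw phenotype. Column-group name lists identify covariates
    and PCs so downstream design matrices can be assembled by name.
    """

    data: pd.DataFrame
    phenotype_col: str = "phenotype_ln"
    covariates: list[str] = field(default_factory=list)
    genotype_pcs: list[str] = field(default_factory=list)
    expression_pcs: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.phenotype_col not in self.data.columns:
            raise ValueError(f"missing phenotype column {self.phenotype_col!r}")
        for c in [*self.covariates, *self.genotype_pcs, *self.expression_pcs]:
            if c not in self.data.columns:
                raise ValueError(f"missing declared column {c!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index.astype(str))

    def phenotype(self) -> np.ndarray:
        return self.data[self.phenotype_col].to_numpy(dtype=float)

    def design(self, columns: list[str], intercept: bool = True) -> np.ndarray:
        """Assemble a design matrix from named columns (prepends intercept)."""
        X = self.data[columns].to_numpy(dtype=float)
        if intercept:
            X = np.column_stack([np.ones(len(X)), X])
        return X

    def aligned_to(self, sample_ids: list[str]) -> "SampleTable":
        return replace(self, data=self.data.loc[sample_ids])


def read_sample_table(
    path: str | Path,
    phenotype_col: str = "phenotype_ln",
    covariates: list[str] | None = None,
) -> SampleTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return SampleTable(df, phenotype_col=phenotype_col, covariates=covariates or [])


def write_sample_table(st: SampleTable, path: str | Path) -> None:
    st.data.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# SummaryStatsTable
# ---------------------------------------------------------------------------


@dataclass
class SummaryStatsTable:
    """GWAS summary statistics: one row per SNP with effect-allele-aligned
    beta, SE, p and effect-allele frequency."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SUMSTATS_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(
                f"summary statistics missing columns {missing}; expected {SUMSTATS_COLUMNS}"
            )
        self.data = self.data[SUMSTATS_COLUMNS].reset_index(drop=True)
        if (self.data["se"] <= 0).any():
            raise ValueError("se must be positive")
        p = self.data["p"]
        if ((p <= 0) | (p > 1)).any():
            raise ValueError("p must be in (0, 1]")
        eaf = self.data["eaf"].dropna()
        if ((eaf <= 0) | (eaf >= 1)).any():
            raise ValueError("eaf must be in (0, 1)")

    def __len__(self) -> int:
        return len(self.data)


def read_summary_stats(
    path: str | Path, column_map: dict[str, str] | None = None
) -> SummaryStatsTable:
    """Read a summary-statistics TSV.

    ``column_map`` maps the file's header names onto the canonical names
    ``snp_id, effect_allele, other_allele, beta, se, p, eaf``. Allele
    columns are upper-cased; rows with ``se <= 0`` are rejected with a
    logged count.
    """
    df = pd.read_csv(path, sep="\t")
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in SUMSTATS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"summary statistics missing columns {missing}; expected {SUMSTATS_COLUMNS}"
        )
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()
    bad = df["se"] <= 0
    if bad.any():
        logger.warning("rejecting %d row(s) with se <= 0", int(bad.sum()))
        df = df[~bad]
    return SummaryStatsTable(df)


def write_summary_stats(ss: SummaryStatsTable, path: str | Path) -> None:
    ss.data.to_csv(path, sep="\t", index=False)


def write_results(tables: dict[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write each result table as ``<name>.tsv`` under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in tables.items():
        p = out_dir / f"{name}.tsv"
        table.to_csv(p, sep="\t", index=False)
        written.append(p)
    return written
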