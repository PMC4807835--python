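"""Readers/writers for external formats and sample alignment.

Conventions
-----------
* Genomic coordinates are 1-based inclusive everywhere, including the
  BED-like annotation table (declared in its header comment).
* Dosages are additive alt-allele counts in {0, 1, 2}; missing calls are
  NaN.  Multi-allelic VCF records are rejected: the analysis is defined on
  biallelic dosages only.
* Missing dosages are NOT imputed at read time — QC must see true
  missingness; mean imputation happens just before regression.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

REQUIRED_META_COLUMNS = (
    "sample_id",
    "individual_id",
    "cell_type",
    "disease",
    "batch",
    "sex",
)


class FormatError(ValueError):
    """A file violated the expected external-format contract."""


@dataclasses.dataclass
class GenotypeMatrix:
    """Additive dosage matrix: individuals x SNPs.

    Attributes
    ----------
    dosage : ndarray, shape (n_individuals, n_snps)
        Values in {0, 1, 2} or NaN for missing calls.
    snp_meta : DataFrame indexed by SNP id
        Columns ``chrom``, ``pos`` (1-based), ``ref``, ``alt``.
    individual_ids : list of str
    """

    dosage: np.ndarray
    snp_meta: pd.DataFrame
    individual_ids: list[str]

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.individual_ids), len(self.snp_meta)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.individual_ids)} individuals x {len(self.snp_meta)} SNPs"
            )
        if self.snp_meta.index.duplicated().any():
            dups = self.snp_meta.index[self.snp_meta.index.duplicated()].tolist()
            raise ValueError(f"duplicated SNP ids: {dups[:5]}")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("duplicated individual ids")

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    @property
    def snp_ids(self) -> pd.Index:
        return self.snp_meta.index

    def maf(self) -> np.ndarray:
        """Minor allele frequency per SNP from non-missing dosages."""
        with np.errstate(invalid="ignore"):
            p = np.nanmean(self.dosage, axis=0) / 2.0
        return np.minimum(p, 1.0 - p)

    def missing_rate(self) -> np.ndarray:
        return np.mean(np.isnan(self.dosage), axis=0)

    def subset_snps(self, mask_or_ids) -> "GenotypeMatrix":
        if isinstance(mask_or_ids, (list, pd.Index, np.ndarray)) and not (
            isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype == bool
        ):
            idx = self.snp_meta.index.get_indexer(mask_or_ids)
            if (idx < 0).any():
                raise KeyError("unknown SNP ids requested")
        else:
            idx = np.flatnonzero(mask_or_ids)
        return GenotypeMatrix(
            self.dosage[:, idx], self.snp_meta.iloc[idx].copy(), list(self.individual_ids)
        )

    def subset_individuals(self, ids: list[str]) -> "GenotypeMatrix":
        pos = {iid: i for i, iid in enumerate(self.individual_ids)}
        try:
            rows = [pos[i] for i in ids]
        except KeyError as exc:
            raise KeyError(f"individual {exc} not in genotype data") from exc
        return GenotypeMatrix(self.dosage[rows], self.snp_meta.copy(), list(ids))


@dataclasses.dataclass
class ExpressionMatrix:
    """Expression values (samples x probesets, log2 scale) for one cell type.

    ``covariates`` is indexed by sample id and carries at least
    ``individual_id``, ``disease`` (0/1), ``batch`` and ``sex``.
    """

    values: pd.DataFrame
    cell_type: str
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicated sample ids in expression matrix")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise FormatError(f"duplicated probeset ids: {dups[:5]}")
        missing = self.values.index.difference(self.covariates.index)
        if len(missing):
            raise FormatError(
                f"samples absent from metadata: {sorted(missing)[:10]}"
            )
        self.covariates = self.covariates.loc[self.values.index]

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def probeset_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return len(self.values)

    @property
    def individual_ids(self) -> list[str]:
        return self.covariates["individual_id"].tolist()

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[sample_ids].copy(),
            self.cell_type,
            self.covariates.loc[sample_ids].copy(),
        )

    def subset_probesets(self, probesets) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[:, list(probesets)].copy(), self.cell_type, self.covariates.copy()
        )

    def with_values(self, values: pd.DataFrame) -> "ExpressionMatrix":
        return ExpressionMatrix(values, self.cell_type, self.covariates.copy())


@dataclasses.dataclass
class Annotation:
    """Probeset positions: gene_id, chrom, start, end (1-based incl.), strand."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene_id", "chrom", "start", "end", "strand"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"annotation missing columns: {sorted(missing)}")
        bad = self.table["start"] > self.table["end"]
        if bad.any():
            raise FormatError(
                f"annotation rows with start > end: {self.table.index[bad].tolist()[:5]}"
            )

    @property
    def probeset_ids(self) -> pd.Index:
        return self.table.index


def _parse_gt(gt: str):
    """Alt-allele dosage from an unphased/phased GT string; None = missing."""
    alleles = gt.replace("|", "/").split("/")
    if "." in alleles:
        return None
    return sum(int(a) for a in alleles)


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Read a VCF (4.x, GT field) or dosage TSV into a GenotypeMatrix.

    TSV dialect: rows = SNPs, columns = individuals, first columns
    ``snp_id, chrom, pos, ref, alt`` then one column per individual.
    """
    path = Path(path)
    if path.suffix in {".vcf", ".gz"} or path.name.endswith(".vcf.gz"):
        return _read_vcf(path)
    return _read_dosage_tsv(path)


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    rows, meta = [], []
    for i, variant in enumerate(vcf, start=1):
        if len(variant.ALT) != 1:
            raise FormatError(
                f"multi-allelic site {variant.ID or variant.CHROM + ':' + str(variant.POS)} "
                f"(record {i}): split or drop before import"
            )
        # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        gt = variant.gt_types.astype(float)
        dos = np.where(gt == 0, 0.0, np.where(gt == 1, 1.0, np.where(gt == 3, 2.0, np.nan)))
        rows.append(dos)
        meta.append(
            {
                "snp_id": variant.ID or f"{variant.CHROM}:{variant.POS}",
                "chrom": variant.CHROM,
                "pos": variant.POS,
                "ref": variant.REF,
                "alt": variant.ALT[0],
            }
        )
    if not rows:
        raise FormatError(f"no variant records in {path}")
    snp_meta = pd.DataFrame(meta).set_index("snp_id")
    return GenotypeMatrix(np.vstack(rows).T, snp_meta, individuals)


def _read_dosage_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", comment="#")
    fixed = ["snp_id", "chrom", "pos", "ref", "alt"]
    missing = [c for c in fixed if c not in df.columns]
    if missing:
        raise FormatError(f"dosage TSV {path} missing columns {missing}")
    individuals = [c for c in df.columns if c not in fixed]
    dosage = df[individuals].to_numpy(dtype=float).T
    ok = np.isnan(dosage) | np.isin(dosage, (0.0, 1.0, 2.0))
    if not ok.all():
        bad_snp = df["snp_id"].iloc[int(np.argwhere(~ok)[0][1])]
        raise FormatError(f"non-dosage value at SNP {bad_snp} in {path}")
    return GenotypeMatrix(dosage, df.set_index("snp_id")[["chrom", "pos", "ref", "alt"]], individuals)


def read_expression(path: str | Path, meta_path: str | Path, cell_type: str | None = None) -> ExpressionMatrix:
    """Read an expression TSV (rows = probesets, header = sample ids) plus metadata.

    When ``cell_type`` is None it is taken from the metadata rows of the
    samples present in the file (which must then agree on a single label).
    """
    raw = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if raw.index.duplicated().any():
        dups = raw.index[raw.index.duplicated()].tolist()
        raise FormatError(f"duplicated probeset rows in {path}: {dups[:5]}")
    values = raw.T  # stored probesets x samples; normalize to samples x probesets
    values.index.name = "sample_id"

    meta = pd.read_csv(meta_path, sep="\t", comment="#", dtype={"sample_id": str, "individual_id": str})
    missing_cols = [c for c in REQUIRED_META_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise FormatError(f"metadata {meta_path} missing columns: {missing_cols}")
    meta = meta.set_index("sample_id")
    unknown = values.index.difference(meta.index)
    if len(unknown):
        raise FormatError(f"samples absent from metadata: {sorted(unknown)[:10]}")
    cov = meta.loc[values.index]
    if cell_type is None:
        labels = cov["cell_type"].unique()
        if len(labels) != 1:
            raise FormatError(f"ambiguous cell type for {path}: {labels.tolist()}")
        cell_type = str(labels[0])
    return ExpressionMatrix(values, cell_type, cov)


def align_samples(
    geno: GenotypeMatrix, expr: ExpressionMatrix
) -> tuple[GenotypeMatrix, ExpressionMatrix, list[str]]:
    """Restrict both matrices to shared individuals, identical row order.

    Returns the aligned pair plus the ids dropped from either side.  Order
    of the output is the sorted intersection, so alignment is invariant to
    input ordering and idempotent.
    """
    expr_ind = expr.covariates["individual_id"]
    shared = sorted(set(geno.individual_ids) & set(expr_ind))
    if not shared:
        raise ValueError("no individuals shared between genotype and expression data")
    dropped = sorted(
        (set(geno.individual_ids) | set(expr_ind)) - set(shared)
    )
    geno_out = geno.subset_individuals(shared)
    ind_to_sample = {ind: s for s, ind in expr_ind.items()}
    expr_out = expr.subset_samples([ind_to_sample[i] for i in shared])
    return geno_out, expr_out, dropped


def read_gwas_catalog(path: str | Path) -> pd.DataFrame:
    """Read a GWAS catalogue table; deduplicate on (rsid, trait)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in ("rsid", "trait") if c not in df.columns]
    if missing:
        raise FormatError(f"GWAS catalogue {path} missing columns: {missing}")
    if "source" not in df.columns:
        df["source"] = "catalog"
    return df.drop_duplicates(subset=["rsid", "trait"]).reset_index(drop=True)


def read_annotation(path: str | Path) -> Annotation:
    df = pd.read_csv(path, sep="\t", comment="#")
    if "probeset" not in df.columns:
        raise FormatError(f"annotation {path} missing 'probeset' column")
    return Annotation(df.set_index("probeset"))


def impute_missing_dosage(dosage: np.ndarray) -> np.ndarray:
    """Mean-impute missing dosages per SNP (columns); used just before regression."""
    out = dosage.copy()
    col_mean = np.nanmean(np.where(np.isnan(out), np.nan, out), axis=0)
    col_mean = np.nan_to_num(col_mean, nan=0.0)
    nan_r, nan_c = np.nonzero(np.isnan(out))
    out[nan_r, nan_c] = col_mean[nan_c]
    return out
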