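"""Synthetic genotype + multi-cell-type expression cohorts with known truth.

The generator emulates the design of a multi-cell-type eQTL study of
~130-150 individuals: five leucocyte subsets with unequal per-cell-type
sample availability (whole-sample dropout), additive dosage genotypes with
MAF >= 0.05 arranged in LD blocks, additive cis effects whose
presence/absence across cell types follows a configurable configuration
distribution, disease-specific (genotype x disease) effects, additive
per-gene batch offsets, and Gaussian residual noise.

LD is simulated by block-copy-with-flips: SNPs within a block copy the
block head's dosage vector with a per-individual flip probability, which
produces a graded r^2 decay adequate to exercise proxy lookup and
conditional analysis without a coalescent simulator.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from mceqtl.ioformats import Annotation, ExpressionMatrix, GenotypeMatrix

DEFAULT_CELL_TYPES = ("CD4", "CD8", "CD14", "CD16", "PLT")


def _default_config_probs(n_cell_types: int = 5) -> dict[str, float]:
    """Prior over eQTL configurations: null, all-active, each singleton.

    Mass reflects the study's finding that full sharing dominates and
    single-cell-type eQTLs are a minority: 70% of genes have no eQTL; of
    eQTL genes, ~55% fully shared, ~25% split evenly over singletons, and
    ~20% over a few intermediate (lineage-like) patterns.
    """
    s = n_cell_types
    probs: dict[str, float] = {"0" * s: 0.70}
    probs["1" * s] = 0.30 * 0.55
    for i in range(s):
        bits = ["0"] * s
        bits[i] = "1"
        probs["".join(bits)] = 0.30 * 0.25 / s
    # lymphoid-like pair (first two) and myeloid-like pair (next two)
    inter = []
    if s >= 2:
        bits = ["0"] * s
        bits[0] = bits[1] = "1"
        inter.append("".join(bits))
    if s >= 4:
        bits = ["0"] * s
        bits[2] = bits[3] = "1"
        inter.append("".join(bits))
    for b in inter:
        probs[b] = 0.30 * 0.20 / len(inter)
    total = sum(probs.values())
    return {k: v / total for k, v in probs.items()}


@dataclasses.dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the study design: 140 individuals, 5 cell types with
    per-cell-type dropout, ~10 cis SNPs per gene in LD blocks of 5,
    standardized effect sizes in [0.4, 0.9], 60% diseased (patient-heavy
    cohort), 3 batches.
    """

    n_individuals: int = 140
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    n_genes: int = 100
    snps_per_gene: int = 10
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 5
    ld_flip_prob: float = 0.05
    config_probs: dict[str, float] | None = None
    effect_sd_range: tuple[float, float] = (0.4, 0.9)
    gxd_fraction: float = 0.0
    disease_fraction: float = 0.6
    opposite_sign_fraction: float = 0.0
    batch_count: int = 3
    batch_sd: float = 0.3
    noise_sd: float = 1.0
    residual_corr: float = 0.0
    dropout_per_cell_type: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 20:
            raise ValueError("n_individuals must be >= 20")
        if not (0.05 <= self.maf_range[0] <= self.maf_range[1] <= 0.5):
            raise ValueError("maf_range must lie within [0.05, 0.5]")
        for name in ("gxd_fraction", "disease_fraction", "opposite_sign_fraction",
                     "dropout_per_cell_type", "ld_flip_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.config_probs is None:
            self.config_probs = _default_config_probs(len(self.cell_types))
        total = sum(self.config_probs.values())
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"config_probs must sum to 1, got {total}")
        s = len(self.cell_types)
        for key in self.config_probs:
            if len(key) != s or set(key) - {"0", "1"}:
                raise ValueError(f"bad configuration key {key!r} for {s} cell types")

    @property
    def n_snps(self) -> int:
        return self.n_genes * self.snps_per_gene


@dataclasses.dataclass
class GroundTruth:
    """Per-gene simulation truth.

    ``table`` is indexed by probeset id with columns: gene_id, causal_snp,
    configuration (bitstring over cell types), gxd (bool), and one
    ``beta_<cell_type>`` column per cell type.  ``sample_masks`` maps cell
    type -> boolean array over individuals (True = expression observed).
    """

    table: pd.DataFrame
    sample_masks: dict[str, np.ndarray]
    cell_types: tuple[str, ...]

    def __post_init__(self) -> None:
        beta_cols = [f"beta_{c}" for c in self.cell_types]
        betas = self.table[beta_cols].to_numpy()
        configs = np.array(
            [[int(b) for b in cfg] for cfg in self.table["configuration"]]
        )
        if not ((configs == 0) == (betas == 0.0)).all():
            raise ValueError("configuration bits must match non-zero betas exactly")


def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Draw dosage genotypes with LD-block structure.

    Each block head is Binomial(2, MAF) per individual; subsequent SNPs in
    the block copy the head with per-individual flip probability
    ``ld_flip_prob`` (a flipped call is redrawn from the head's marginal).
    SNPs whose realized MAF falls below 0.01 are resampled.  Genes are laid
    out on chromosomes of 20 genes each, 1 Mb apart, with their cis SNPs
    spread across the gene body +/- 50 kb.
    """
    if cfg.n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_individuals, cfg.n_snps
    dosage = np.empty((n, m))
    mafs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)
    block = max(1, cfg.ld_block_size)
    for j in range(m):
        head = j - (j % block)
        for _attempt in range(100):
            if j == head:
                col = rng.binomial(2, mafs[j], size=n).astype(float)
            else:
                col = dosage[:, head].copy()
                flip = rng.random(n) < cfg.ld_flip_prob
                col[flip] = rng.binomial(2, mafs[head], size=int(flip.sum()))
            p = col.mean() / 2.0
            if min(p, 1 - p) >= 0.01:
                break
        dosage[:, j] = col

    meta = []
    for j in range(m):
        gene = j // cfg.snps_per_gene
        within = j % cfg.snps_per_gene
        chrom = f"chr{gene // 20 + 1}"
        gene_start = 1_000_000 * (gene % 20 + 1)
        pos = gene_start - 50_000 + within * (110_000 // max(1, cfg.snps_per_gene))
        meta.append(
            {"snp_id": f"rs{j + 1:06d}", "chrom": chrom, "pos": max(1, pos),
             "ref": "A", "alt": "G"}
        )
    snp_meta = pd.DataFrame(meta).set_index("snp_id")
    individuals = [f"I{i + 1:04d}" for i in range(n)]
    return GenotypeMatrix(dosage, snp_meta, individuals)


def make_annotation(cfg: SimConfig) -> Annotation:
    """Gene bodies consistent with the SNP layout from simulate_genotypes."""
    rows = []
    for gene in range(cfg.n_genes):
        chrom = f"chr{gene // 20 + 1}"
        start = 1_000_000 * (gene % 20 + 1)
        rows.append(
            {"probeset": f"PS{gene + 1:05d}", "gene_id": f"G{gene + 1:05d}",
             "chrom": chrom, "start": start, "end": start + 10_000, "strand": "+"}
        )
    return Annotation(pd.DataFrame(rows).set_index("probeset"))


def _draw_truth(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    s = len(cfg.cell_types)
    keys = sorted(cfg.config_probs)
    probs = np.array([cfg.config_probs[k] for k in keys])
    chosen = rng.choice(len(keys), size=cfg.n_genes, p=probs)
    rows = []
    for gene in range(cfg.n_genes):
        config = keys[chosen[gene]]
        causal = gene * cfg.snps_per_gene + int(rng.integers(cfg.snps_per_gene))
        base_beta = rng.uniform(*cfg.effect_sd_range)
        sign = rng.choice([-1.0, 1.0])
        bits = np.array([int(b) for b in config])
        betas = bits * base_beta * sign
        if bits.sum() >= 2 and rng.random() < cfg.opposite_sign_fraction:
            active = np.flatnonzero(bits)
            betas[rng.choice(active)] *= -1.0
        gxd = bool(bits.any()) and (rng.random() < cfg.gxd_fraction)
        row = {"probeset": f"PS{gene + 1:05d}", "gene_id": f"G{gene + 1:05d}",
               "causal_snp": f"rs{causal + 1:06d}",
               "configuration": config, "gxd": gxd}
        for c, b in zip(cfg.cell_types, betas):
            row[f"beta_{c}"] = float(b)
        rows.append(row)
    return pd.DataFrame(rows).set_index("probeset")


def simulate_cohort(
    cfg: SimConfig, geno: GenotypeMatrix
) -> tuple[list[ExpressionMatrix], GroundTruth]:
    """Generate per-cell-type expression with known eQTL structure.

    Expression of gene j for individual i in cell type c:

        y = mu_j + beta_jc * g_ij * (d_i if GxD else 1) + batch_offset + eps

    with eps ~ N(0, noise_sd^2), optionally correlated across cell types of
    the same individual (equicorrelation ``residual_corr``).  Per-cell-type
    whole-sample dropout masks emulate unequal sample availability.
    """
    if geno.n_snps != cfg.n_snps or geno.n_individuals != cfg.n_individuals:
        raise ValueError("genotype matrix does not match cfg dimensions")
    rng = np.random.default_rng(cfg.seed + 1)
    n, s = cfg.n_individuals, len(cfg.cell_types)
    truth = _draw_truth(cfg, rng)

    disease = (rng.random(n) < cfg.disease_fraction).astype(int)
    batch = rng.integers(cfg.batch_count, size=n)
    sex = rng.choice(["F", "M"], size=n)
    mu = rng.normal(7.0, 1.5, size=cfg.n_genes)
    batch_offsets = rng.normal(0.0, cfg.batch_sd, size=(cfg.batch_count, cfg.n_genes))

    # residuals: equicorrelated across cell types via shared individual term
    rho = cfg.residual_corr
    shared_sd = np.sqrt(rho) * cfg.noise_sd
    own_sd = np.sqrt(1.0 - rho) * cfg.noise_sd
    shared = rng.normal(0.0, 1.0, size=(n, cfg.n_genes)) * shared_sd

    causal_idx = geno.snp_meta.index.get_indexer(truth["causal_snp"])
    g_causal = geno.dosage[:, causal_idx]  # n x genes
    g_causal = np.where(np.isnan(g_causal), np.nanmean(g_causal, axis=0), g_causal)

    masks: dict[str, np.ndarray] = {}
    exprs: list[ExpressionMatrix] = []
    gxd = truth["gxd"].to_numpy()
    for ci, cell in enumerate(cfg.cell_types):
        betas = truth[f"beta_{cell}"].to_numpy()
        dose_mult = np.where(gxd[None, :], disease[:, None], 1.0)
        signal = mu[None, :] + betas[None, :] * g_causal * dose_mult
        eps = shared + rng.normal(0.0, 1.0, size=(n, cfg.n_genes)) * own_sd
        y = signal + batch_offsets[batch] + eps

        keep = rng.random(n) >= cfg.dropout_per_cell_type
        if keep.sum() < 10:
            keep[:] = True
        masks[cell] = keep
        sample_ids = [f"{iid}_{cell}" for iid, k in zip(geno.individual_ids, keep) if k]
        values = pd.DataFrame(
            y[keep], index=pd.Index(sample_ids, name="sample_id"), columns=truth.index
        )
        cov = pd.DataFrame(
            {
                "individual_id": [i for i, k in zip(geno.individual_ids, keep) if k],
                "cell_type": cell,
                "disease": disease[keep],
                "batch": [f"B{b + 1}" for b in batch[keep]],
                "sex": sex[keep],
                "timepoint": "t0",
            },
            index=values.index,
        )
        exprs.append(ExpressionMatrix(values, cell, cov))

    return exprs, GroundTruth(truth, masks, cfg.cell_types)


def write_fixture_bundle(cfg: SimConfig, out_dir: str | Path) -> dict:
    """Write a complete synthetic study to disk; returns the manifest.

    Emits a VCF 4.2 (unphased GT), one expression TSV per cell type, the
    annotation table, sample metadata, ground truth, and a JSON manifest.
    Values round-trip through the ioformats readers (dosages exactly,
    expression to 6 decimals).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    geno = simulate_genotypes(cfg)
    exprs, truth = simulate_cohort(cfg, geno)
    ann = make_annotation(cfg)

    vcf_path = out / "genotypes.vcf"
    _write_vcf(vcf_path, geno, cfg.seed)

    meta_rows = []
    expr_files = {}
    for expr in exprs:
        fname = f"expression_{expr.cell_type}.tsv"
        with open(out / fname, "w") as fh:
            fh.write(f"# mceqtl synthetic fixture, seed={cfg.seed}\n")
            expr.values.T.round(6).to_csv(fh, sep="\t", index_label="probeset")
        expr_files[expr.cell_type] = fname
        meta_rows.append(expr.covariates.reset_index())
    meta = pd.concat(meta_rows, ignore_index=True)
    meta.to_csv(out / "samples.tsv", sep="\t", index=False)

    with open(out / "annotation.tsv", "w") as fh:
        fh.write("# coordinates 1-based inclusive\n")
        ann.table.to_csv(fh, sep="\t", index_label="probeset")
    truth.table.to_csv(out / "ground_truth.tsv", sep="\t", index_label="probeset")

    manifest = {
        "seed": cfg.seed,
        "n_individuals": cfg.n_individuals,
        "cell_types": list(cfg.cell_types),
        "genotypes": "genotypes.vcf",
        "expression": expr_files,
        "metadata": "samples.tsv",
        "annotation": "annotation.tsv",
        "ground_truth": "ground_truth.tsv",
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _write_vcf(path: Path, geno: GenotypeMatrix, seed: int) -> None:
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=mceqtl synthetic fixture seed={seed}\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = geno.snp_meta["chrom"].unique()
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(geno.individual_ids) + "\n")
        for j, (snp_id, row) in enumerate(geno.snp_meta.iterrows()):
            calls = "\t".join(
                gt_map.get(d, "./.") for d in geno.dosage[:, j]
            )
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{snp_id}\t{row['ref']}\t{row['alt']}"
                f"\t.\tPASS\t.\tGT\t{calls}\n"
            )
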