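"""End-to-end orchestration of the synthetic study.

Stages: simulate (or load) a cohort -> genotype QC -> expression variance
filter -> adjustment (latent factors for scans/BMA, batch location/scale
for the interaction analysis) -> per-cell-type cis scans with plug-in FDR
-> joint BMA across cell types -> two-step genotype x disease interaction
-> sharing summaries.  All randomness derives from the seeds recorded in
the RunConfig, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from mceqtl import bma, cis_scan, interaction, preprocess, sharing
from mceqtl.ioformats import (
    Annotation,
    ExpressionMatrix,
    GenotypeMatrix,
    align_samples,
    read_annotation,
    read_expression,
    read_genotypes,
)
from mceqtl.simulate import SimConfig, make_annotation, simulate_cohort, simulate_genotypes

logger = logging.getLogger("mceqtl")


@dataclasses.dataclass
class RunConfig:
    """Thresholds and seeds for a full run; defaults follow the study design."""

    window: int = 100_000
    maf_scan: float = 0.05
    maf_interaction: float = 0.10
    fdr_scan: float = 0.05
    fdr_bma: float = 0.05
    fdr_interaction: float = 0.15
    alpha1: float = 5e-5
    n_permutations: int = 3
    n_factors: int = 5
    seed: int = 0
    covariates: tuple[str, ...] = ("disease",)

    def __post_init__(self) -> None:
        for name in ("maf_scan", "maf_interaction", "fdr_scan", "fdr_bma",
                     "fdr_interaction", "alpha1"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")


@dataclasses.dataclass
class StudyData:
    geno: GenotypeMatrix
    exprs: list[ExpressionMatrix]
    annotation: Annotation
    truth_table: pd.DataFrame | None = None


def make_synthetic_study(sim_cfg: SimConfig) -> StudyData:
    geno = simulate_genotypes(sim_cfg)
    exprs, truth = simulate_cohort(sim_cfg, geno)
    return StudyData(geno, exprs, make_annotation(sim_cfg), truth.table)


def load_study(fixture_dir: str | Path) -> StudyData:
    fixture_dir = Path(fixture_dir)
    manifest = json.loads((fixture_dir / "manifest.json").read_text())
    geno = read_genotypes(fixture_dir / manifest["genotypes"])
    exprs = [
        read_expression(fixture_dir / fname, fixture_dir / manifest["metadata"], cell)
        for cell, fname in manifest["expression"].items()
    ]
    ann = read_annotation(fixture_dir / manifest["annotation"])
    truth_path = fixture_dir / manifest.get("ground_truth", "")
    truth = pd.read_csv(truth_path, sep="\t", index_col=0) if truth_path.is_file() else None
    return StudyData(geno, exprs, ann, truth)


def run_scan_pipeline(
    data: StudyData, cfg: RunConfig, adjust: bool = True
) -> dict[str, dict]:
    """Per-cell-type cis scan with plug-in FDR.

    Returns per cell type: the records frame, the PluginFdrResult, and the
    declared (probeset, snp) set.
    """
    geno_qc, snp_report = preprocess.qc_snps(data.geno, maf_min=cfg.maf_scan)
    logger.info("SNP QC removed %s", snp_report.removed_counts)
    windows = cis_scan.cis_window(data.annotation, geno_qc.snp_meta, cfg.window)
    out: dict[str, dict] = {}
    for expr in data.exprs:
        g_sub, e_sub, dropped = align_samples(geno_qc, expr)
        if adjust:
            e_sub = preprocess.adjust_expression(
                e_sub, mode="factor", n_factors=cfg.n_factors
            )
        records = cis_scan.scan_cell_type(e_sub, g_sub, windows, cfg.covariates)
        closure = cis_scan.scan_with_permutation(e_sub, g_sub, windows, cfg.covariates)
        fdr_res = cis_scan.plugin_fdr(
            records, closure, cfg.n_permutations, cfg.fdr_scan, seed=cfg.seed
        )
        declared_pairs = set(
            zip(fdr_res.declared["probeset"], fdr_res.declared["snp"])
        )
        logger.info(
            "scan %s: n=%d, %d pairs tested, %d declared at %.0f%% FDR",
            expr.cell_type, e_sub.n_samples, len(records),
            len(declared_pairs), 100 * cfg.fdr_scan,
        )
        out[expr.cell_type] = {
            "records": records,
            "fdr": fdr_res,
            "declared_pairs": declared_pairs,
            "declared_genes": {p for p, _ in declared_pairs},
        }
    return out


def run_bma_pipeline(data: StudyData, cfg: RunConfig) -> dict:
    """Joint BMA over subgroups on quantile-normal transformed expression."""
    geno_qc, _ = preprocess.qc_snps(data.geno, maf_min=cfg.maf_scan)
    windows = cis_scan.cis_window(data.annotation, geno_qc.snp_meta, cfg.window)
    exprs_t = []
    for expr in data.exprs:
        adj = preprocess.adjust_expression(expr, mode="factor", n_factors=cfg.n_factors)
        exprs_t.append(preprocess.quantile_normal_transform(adj, seed=cfg.seed))
    results, hp, declared = bma.run_bma(
        exprs_t, geno_qc, windows, cfg.covariates, fdr_target=cfg.fdr_bma
    )
    subgroups = [e.cell_type for e in data.exprs]
    logger.info(
        "BMA: pi0=%.3f, %d/%d genes declared at %.0f%% Bayes FDR",
        hp.pi0, len(declared), len(results), 100 * cfg.fdr_bma,
    )
    return {
        "results": results,
        "hyperparams": hp,
        "declared": declared,
        "subgroups": subgroups,
        "table": bma.results_table(results, subgroups),
    }


def run_interaction_pipeline(data: StudyData, cfg: RunConfig) -> dict[str, interaction.InteractionScanResult]:
    """Two-step G x D scan per cell type on batch-adjusted expression."""
    geno_qc, _ = preprocess.qc_snps(data.geno, maf_min=cfg.maf_scan)
    windows = cis_scan.cis_window(data.annotation, geno_qc.snp_meta, cfg.window)
    out = {}
    for expr in data.exprs:
        g_sub, e_sub, _ = align_samples(geno_qc, expr)
        e_adj = preprocess.adjust_expression(e_sub, mode="batch")
        res = interaction.two_step_scan(
            e_adj, g_sub, windows, cfg.alpha1, cfg.maf_interaction, cfg.fdr_interaction
        )
        logger.info(
            "interaction %s: %d step-2 tests, %d declared at %.0f%% BH FDR",
            expr.cell_type, res.n_tested, len(res.declared), 100 * cfg.fdr_interaction,
        )
        out[expr.cell_type] = res
    return out


def run_all(
    data: StudyData, cfg: RunConfig, out_dir: str | Path | None = None
) -> dict:
    """Scan + BMA + interaction + sharing; optionally write result TSVs."""
    scans = run_scan_pipeline(data, cfg)
    bma_out = run_bma_pipeline(data, cfg)
    inter = run_interaction_pipeline(data, cfg)

    declared_sets = {c: s["declared_genes"] for c, s in scans.items()}
    naive = sharing.naive_sharing_summary(declared_sets)
    joint = sharing.bma_sharing_summary(
        bma_out["results"], bma_out["declared"], bma_out["subgroups"]
    )
    result = {
        "scans": scans,
        "bma": bma_out,
        "interaction": inter,
        "naive_sharing": naive,
        "bma_sharing": joint,
    }
    if out_dir is not None:
        write_artifacts(result, cfg, Path(out_dir))
    return result


def _float_fmt(df: pd.DataFrame) -> pd.DataFrame:
    return df.round(10)


def write_artifacts(result: dict, cfg: RunConfig, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    header = f"# mceqtl results, seed={cfg.seed}\n"
    for cell, s in result["scans"].items():
        path = out_dir / f"scan_{cell}.tsv"
        rec = s["records"].copy()
        declared = s["declared_pairs"]
        rec["declared_5fdr"] = [
            (p, sn) in declared for p, sn in zip(rec["probeset"], rec["snp"])
        ]
        with open(path, "w") as fh:
            fh.write(header)
            _float_fmt(rec).to_csv(fh, sep="\t", index=False)
    with open(out_dir / "bma_genes.tsv", "w") as fh:
        fh.write(header)
        _float_fmt(result["bma"]["table"]).to_csv(fh, sep="\t")
    for cell, res in result["interaction"].items():
        with open(out_dir / f"interaction_{cell}.tsv", "w") as fh:
            fh.write(header)
            _float_fmt(res.records).to_csv(fh, sep="\t", index=False)
    summary = {
        "pi0": result["bma"]["hyperparams"].pi0,
        "n_bma_declared": len(result["bma"]["declared"]),
        "naive_jaccard": result["naive_sharing"].jaccard_matrix.to_dict(),
        "bma_jaccard": result["bma_sharing"].jaccard_matrix.to_dict(),
        "naive_histogram": {int(k): int(v) for k, v in result["naive_sharing"].histogram.items()},
        "bma_histogram": {int(k): int(v) for k, v in result["bma_sharing"].histogram.items()},
        "interaction_declared": {
            c: int(len(r.declared)) for c, r in result["interaction"].items()
        },
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))


def setup_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.INFO if verbose else logging.WARNING)
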