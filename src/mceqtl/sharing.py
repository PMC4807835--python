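"""Sharing and overlap statistics for multi-cell-type eQTL results.

Quantifies how eQTLs distribute across cell types: per-gene presence sets
(from per-cell-type FDR membership, or from joint-model MAP configurations
/ activity posteriors), histograms over the number of cell types sharing
an eQTL, pairwise Jaccard coefficients, opposite-direction effect pairs,
in-sample LD r^2, GWAS-catalogue overlap, and hierarchical clustering of
association-score matrices.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from mceqtl.bma import BmaGeneResult
from mceqtl.ioformats import GenotypeMatrix


def jaccard(a: set, b: set) -> float:
    """|A n B| / |A u B|; 0 when both sets are empty."""
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


@dataclasses.dataclass
class SharingSummary:
    presence: dict[str, set[str]]        # gene -> subgroups where present
    histogram: pd.Series                 # #subgroups -> gene count
    singleton_breakdown: pd.Series       # subgroup -> count of exclusive genes
    jaccard_matrix: pd.DataFrame
    subgroups: list[str]

    @property
    def n_genes(self) -> int:
        return len(self.presence)

    def shared_fraction(self, k: int | None = None) -> float:
        """Fraction of eQTL genes present in exactly k subgroups
        (default: all subgroups)."""
        if self.n_genes == 0:
            return float("nan")
        k = len(self.subgroups) if k is None else k
        return float(self.histogram.get(k, 0)) / self.n_genes


def _summarize(presence: dict[str, set[str]], subgroups: list[str]) -> SharingSummary:
    counts = pd.Series([len(v) for v in presence.values()], dtype=int)
    histogram = counts.value_counts().sort_index()
    singletons = pd.Series(0, index=subgroups, dtype=int)
    for subs in presence.values():
        if len(subs) == 1:
            singletons[next(iter(subs))] += 1
    sets = {sg: {g for g, subs in presence.items() if sg in subs} for sg in subgroups}
    jac = pd.DataFrame(
        [[jaccard(sets[a], sets[b]) for b in subgroups] for a in subgroups],
        index=subgroups, columns=subgroups,
    )
    return SharingSummary(presence, histogram, singletons, jac, subgroups)


def naive_sharing_summary(declared_sets: dict[str, set[str]]) -> SharingSummary:
    """Sharing from per-subgroup significant lists (comparison-of-lists).

    ``declared_sets`` maps subgroup -> set of genes significant at the
    per-subgroup FDR.  For an equal-power comparison the upstream scans
    should have been restricted to individuals with complete data.
    """
    subgroups = list(declared_sets)
    presence: dict[str, set[str]] = {}
    for sg, genes in declared_sets.items():
        for g in genes:
            presence.setdefault(g, set()).add(sg)
    return _summarize(presence, subgroups)


def bma_sharing_summary(
    results: list[BmaGeneResult],
    declared: set[str],
    subgroups: list[str],
    mode: str = "map",
    activity_pp: float = 0.5,
) -> SharingSummary:
    """Sharing from the joint model, over Bayes-FDR-declared genes.

    mode="map" reads presence off the MAP configuration; mode="activity"
    thresholds the per-subgroup activity posterior.
    """
    if mode not in {"map", "activity"}:
        raise ValueError(f"unknown mode {mode!r}")
    presence: dict[str, set[str]] = {}
    for r in results:
        if r.probeset not in declared:
            continue
        if mode == "map":
            subs = {sg for sg, bit in zip(subgroups, r.map_config) if bit == "1"}
        else:
            subs = {sg for sg in subgroups if r.activity_pp[sg] > activity_pp}
        if subs:
            presence[r.probeset] = subs
    return _summarize(presence, subgroups)


def opposite_direction_pairs(
    records_a: pd.DataFrame,
    records_b: pd.DataFrame,
    declared_a: set[tuple[str, str]],
    declared_b: set[tuple[str, str]],
) -> pd.DataFrame:
    """Associations significant in both subgroups with opposite effect signs.

    ``records_*`` are scan frames; ``declared_*`` are (probeset, snp) pairs
    in each subgroup's FDR set.  Returns the full beta-vs-beta table with
    an ``opposite`` flag; allele orientation is asserted via shared SNP ids
    coming from the same genotype matrix.
    """
    both = declared_a & declared_b
    if not both:
        return pd.DataFrame(columns=["probeset", "snp", "beta_a", "beta_b", "opposite"])
    a = records_a.set_index(["probeset", "snp"])["beta"]
    b = records_b.set_index(["probeset", "snp"])["beta"]
    rows = []
    for key in sorted(both):
        beta_a, beta_b = float(a[key]), float(b[key])
        rows.append(
            {"probeset": key[0], "snp": key[1], "beta_a": beta_a, "beta_b": beta_b,
             "opposite": np.sign(beta_a) * np.sign(beta_b) < 0}
        )
    return pd.DataFrame(rows)


def ld_r2(geno: GenotypeMatrix, snp_a: str, snp_b: str) -> float:
    """Squared dosage correlation (composite LD) over shared non-missing calls."""
    ia = geno.snp_meta.index.get_loc(snp_a)
    ib = geno.snp_meta.index.get_loc(snp_b)
    a, b = geno.dosage[:, ia], geno.dosage[:, ib]
    both = ~np.isnan(a) & ~np.isnan(b)
    a, b = a[both], b[both]
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("monomorphic SNP in LD computation")
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def _ld_proxies(geno: GenotypeMatrix, snp: str, r2_min: float) -> list[str]:
    j = geno.snp_meta.index.get_loc(snp)
    a = geno.dosage[:, j]
    if np.nanstd(a) == 0:
        return [snp]
    out = []
    chrom = geno.snp_meta["chrom"]
    target_chrom = chrom.iloc[j]
    for k, other in enumerate(geno.snp_meta.index):
        if chrom.iloc[k] != target_chrom:
            continue
        b = geno.dosage[:, k]
        both = ~np.isnan(a) & ~np.isnan(b)
        if np.std(b[both]) == 0:
            continue
        r2 = np.corrcoef(a[both], b[both])[0, 1] ** 2
        if other == snp or r2 > r2_min:
            out.append(other)
    return out


def gwas_overlap(
    records_by_cell: dict[str, pd.DataFrame],
    fdr_sets: dict[str, set[tuple[str, str]]],
    gwas: pd.DataFrame,
    geno: GenotypeMatrix,
    r2_min: float = 0.8,
    criterion: str = "basic",
) -> pd.DataFrame:
    """Cross-reference GWAS catalogue SNPs (and in-sample LD proxies) with eQTLs.

    basic: the GWAS SNP or a proxy (r^2 > r2_min) is in the 5% FDR set for
    a gene/cell type.  stringent: additionally that eSNP is the gene's
    maximum-chi2 cis SNP in that cell type.  GWAS rsids absent from the
    genotype data are skipped.
    """
    if criterion not in {"basic", "stringent"}:
        raise ValueError(f"unknown criterion {criterion!r}")
    top_snp: dict[str, dict[str, str]] = {}
    if criterion == "stringent":
        for cell, rec in records_by_cell.items():
            ok = rec.loc[~rec["flagged"]]
            idx = ok.groupby("probeset")["chi2"].idxmax()
            top_snp[cell] = dict(zip(ok.loc[idx, "probeset"], ok.loc[idx, "snp"]))
    rows = []
    known = set(geno.snp_meta.index)
    for _, hit in gwas.iterrows():
        rsid = hit["rsid"]
        if rsid not in known:
            continue
        proxies = _ld_proxies(geno, rsid, r2_min)
        for cell, declared in fdr_sets.items():
            for probeset, esnp in declared:
                if esnp not in proxies:
                    continue
                if criterion == "stringent" and top_snp.get(cell, {}).get(probeset) != esnp:
                    continue
                r2 = 1.0 if esnp == rsid else ld_r2(geno, rsid, esnp)
                rows.append(
                    {"gwas_snp": rsid, "trait": hit["trait"], "esnp": esnp,
                     "r2": r2, "probeset": probeset, "cell_type": cell}
                )
    out = pd.DataFrame(
        rows, columns=["gwas_snp", "trait", "esnp", "r2", "probeset", "cell_type"]
    )
    return out.sort_values(["gwas_snp", "trait", "cell_type", "probeset", "esnp"]).reset_index(drop=True)


@dataclasses.dataclass
class ClusterResult:
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_order: np.ndarray
    col_order: np.ndarray


def cluster_scores(score_matrix: pd.DataFrame) -> ClusterResult:
    """Hierarchically cluster an association-score matrix (pairs x subgroups).

    Distance is 1 - Pearson correlation, average linkage — scale-invariant,
    so columns measuring the same sharing pattern merge early.
    """
    if score_matrix.shape[1] < 2:
        raise ValueError("need at least 2 columns to cluster")
    x = score_matrix.to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("score matrix must be finite")

    def corr_dist(mat: np.ndarray) -> np.ndarray:
        c = np.corrcoef(mat)
        c = np.clip(np.nan_to_num(c, nan=0.0), -1.0, 1.0)
        d = 1.0 - c
        np.fill_diagonal(d, 0.0)
        return squareform(d, checks=False)

    col_link = hierarchy.linkage(corr_dist(x.T), method="average")
    if x.shape[0] >= 2:
        row_link = hierarchy.linkage(corr_dist(x), method="average")
        row_order = hierarchy.leaves_list(row_link)
    else:
        row_link = np.empty((0, 4))
        row_order = np.arange(x.shape[0])
    return ClusterResult(row_link, col_link, row_order, hierarchy.leaves_list(col_link))
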