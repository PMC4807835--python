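"""Per-cell-type cis-eQTL association scanning.

The association test is the 1-df additive score test: after fitting the
base model (intercept + covariates), genotype is tested for addition.
With r_y, r_g the residuals of expression and dosage on the base design,

    chi2 = (r_g' r_y)^2 / (sigma0^2 * r_g' r_g),   sigma0^2 = r_y' r_y / n

and p is the upper tail of chi-squared(1).  The reported beta and se come
from the full OLS fit of y on (X, g), so |z|^2 is the Wald statistic and is
close to, but not identical to, the score statistic.

The plug-in FDR estimates the null distribution of the statistic by
permuting expression sample labels against genotype (one permutation per
replicate, applied matrix-wide so gene-gene correlation is preserved),
repeating the whole scan, and setting

    FDR(t) = [mean_b #{null chi2 >= t}] / #{observed chi2 >= t},

monotonized to be non-increasing in t.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from mceqtl.ioformats import (
    Annotation,
    ExpressionMatrix,
    GenotypeMatrix,
    impute_missing_dosage,
)


def cis_window(
    ann: Annotation, snp_meta: pd.DataFrame, w: int = 100_000
) -> dict[str, np.ndarray]:
    """Map probeset -> indices of SNPs within w bases of the gene body.

    A SNP is cis iff it is on the gene's chromosome and
    gene_start - w <= pos <= gene_end + w (1-based inclusive, lower bound
    floored at 1).  Probesets with no cis SNPs map to an empty array.
    """
    out: dict[str, np.ndarray] = {}
    chrom = snp_meta["chrom"].to_numpy()
    pos = snp_meta["pos"].to_numpy()
    for probeset, row in ann.table.iterrows():
        lo = max(1, row["start"] - w)
        hi = row["end"] + w
        mask = (chrom == row["chrom"]) & (pos >= lo) & (pos <= hi)
        out[probeset] = np.flatnonzero(mask)
    return out


@dataclasses.dataclass
class AssocRecord:
    probeset: str
    snp: str
    cell_type: str
    beta: float
    se: float
    z: float
    chi2: float
    p: float
    n_used: int
    flagged: bool = False


def _base_q(x: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the base design, robust to collinear columns."""
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    keep = s > (s[0] * 1e-10 if len(s) and s[0] > 0 else 0)
    return u[:, keep]


def score_test(
    y: np.ndarray, g: np.ndarray, x: np.ndarray,
    probeset: str = "", snp: str = "", cell_type: str = "",
) -> AssocRecord:
    """Score test for adding genotype g to the base model y ~ X."""
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    n = len(y)
    q = _base_q(x)
    r_y = y - q @ (q.T @ y)
    r_g = g - q @ (q.T @ g)
    sgg = float(r_g @ r_g)
    if sgg < 1e-12:
        return AssocRecord(probeset, snp, cell_type, np.nan, np.nan, np.nan,
                           np.nan, np.nan, n, flagged=True)
    sgy = float(r_g @ r_y)
    syy = float(r_y @ r_y)
    sigma0 = syy / n
    chi2 = sgy**2 / (sigma0 * sgg)
    p = float(stats.chi2.sf(chi2, df=1))
    beta = sgy / sgg
    dof = n - x.shape[1] - 1
    rss = syy - beta * sgy
    se = float(np.sqrt(max(rss, 0.0) / max(dof, 1) / sgg))
    z = beta / se if se > 0 else np.nan
    return AssocRecord(probeset, snp, cell_type, beta, se, z, chi2, p, n)


def _scan_arrays(
    y_mat: np.ndarray,
    dosage: np.ndarray,
    x: np.ndarray,
    windows: dict[str, np.ndarray],
    probesets: list[str],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[tuple[int, int]]]:
    """Vectorized score test over all (probeset, cis SNP) pairs.

    Returns (chi2, beta, se) flat arrays plus (probeset_idx, snp_idx) pairs
    in deterministic (probeset, SNP-position) order.
    """
    n = y_mat.shape[0]
    q = _base_q(x)
    r_y = y_mat - q @ (q.T @ y_mat)
    r_g = dosage - q @ (q.T @ dosage)
    gg = np.einsum("ij,ij->j", r_g, r_g)
    syy = np.einsum("ij,ij->j", r_y, r_y)

    chi2_l, beta_l, se_l, pairs = [], [], [], []
    p_cols = x.shape[1]
    for pi, probeset in enumerate(probesets):
        snps = windows.get(probeset, np.array([], dtype=int))
        if len(snps) == 0:
            continue
        ry = r_y[:, pi]
        gy = r_g[:, snps].T @ ry
        sgg = gg[snps]
        ok = sgg > 1e-12
        sigma0 = syy[pi] / n
        with np.errstate(divide="ignore", invalid="ignore"):
            chi2 = np.where(ok, gy**2 / (sigma0 * sgg), np.nan)
            beta = np.where(ok, gy / sgg, np.nan)
            rss = syy[pi] - beta * gy
            se = np.where(ok, np.sqrt(np.maximum(rss, 0.0) / max(n - p_cols - 1, 1) / sgg), np.nan)
        chi2_l.append(chi2)
        beta_l.append(beta)
        se_l.append(se)
        pairs.extend((pi, int(s)) for s in snps)
    if not pairs:
        return np.array([]), np.array([]), np.array([]), []
    return np.concatenate(chi2_l), np.concatenate(beta_l), np.concatenate(se_l), pairs


def scan_cell_type(
    expr: ExpressionMatrix,
    geno: GenotypeMatrix,
    windows: dict[str, np.ndarray],
    covariates: tuple[str, ...] = ("disease",),
) -> pd.DataFrame:
    """Score-test every (probeset, cis SNP) pair in one cell type.

    Samples must already be aligned (one expression row per genotype row,
    same order).  Missing dosages are mean-imputed here.  Returns a tidy
    frame ordered by (probeset, SNP position).
    """
    if expr.n_samples != geno.n_individuals:
        raise ValueError("expression and genotype matrices are not aligned")
    y_mat = expr.values.to_numpy(dtype=float)
    dosage = impute_missing_dosage(geno.dosage)
    x = _covariate_design(expr.covariates, covariates)
    probesets = list(expr.probeset_ids)
    chi2, beta, se, pairs = _scan_arrays(y_mat, dosage, x, windows, probesets)
    n = expr.n_samples
    snp_ids = geno.snp_meta.index.to_numpy()
    snp_pos = geno.snp_meta["pos"].to_numpy()
    snp_chrom = geno.snp_meta["chrom"].to_numpy()
    pi_arr = np.array([p for p, _ in pairs], dtype=int)
    si_arr = np.array([s for _, s in pairs], dtype=int)
    with np.errstate(invalid="ignore"):
        df = pd.DataFrame(
            {
                "probeset": np.array(probesets, dtype=object)[pi_arr],
                "snp": snp_ids[si_arr],
                "chrom": snp_chrom[si_arr],
                "pos": snp_pos[si_arr],
                "cell_type": expr.cell_type,
                "n": n,
                "beta": beta,
                "se": se,
                "z": np.where(se > 0, beta / se, np.nan),
                "chi2": chi2,
                "p": stats.chi2.sf(chi2, df=1),
                "flagged": ~np.isfinite(chi2),
            }
        )
    return df


def _covariate_design(cov: pd.DataFrame, names: tuple[str, ...]) -> np.ndarray:
    cols = [np.ones(len(cov))]
    for name in names:
        if name not in cov.columns:
            raise KeyError(f"covariate {name!r} not in sample metadata")
        col = cov[name]
        if col.dtype == object or str(col.dtype) == "category":
            dummies = pd.get_dummies(col, drop_first=True)
            cols.extend(dummies[c].to_numpy(dtype=float) for c in dummies.columns)
        else:
            cols.append(col.to_numpy(dtype=float))
    return np.column_stack(cols)


@dataclasses.dataclass
class PluginFdrResult:
    n_permutations: int
    target: float
    threshold: float | None          # chi2 threshold t*; None if nothing declared
    fdr_at_threshold: float | None
    declared: pd.DataFrame           # rows of the observed scan with chi2 >= t*
    fdr_curve: pd.DataFrame          # columns: t (observed chi2 desc), fdr


def plugin_fdr(
    records: pd.DataFrame,
    scan_closure,
    n_permutations: int = 3,
    target: float = 0.05,
    seed: int = 0,
    gene_level: bool = False,
) -> PluginFdrResult:
    """Permutation plug-in FDR over a scan's chi2 statistics.

    ``scan_closure(perm)`` must rerun the scan with expression rows permuted
    by the index array ``perm`` and return a records frame of the same
    shape.  ``gene_level`` switches both observed and null statistics to
    per-gene maxima.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    rng = np.random.default_rng(seed)
    obs = records.loc[~records["flagged"]]
    if gene_level:
        obs = obs.loc[obs.groupby("probeset")["chi2"].idxmax()]
    obs_chi2 = obs["chi2"].to_numpy()
    n_samples = int(records["n"].iloc[0]) if len(records) else 0

    null_stats = []
    for _ in range(n_permutations):
        perm = rng.permutation(n_samples)
        null = scan_closure(perm)
        null = null.loc[~null["flagged"]]
        if gene_level:
            null = null.loc[null.groupby("probeset")["chi2"].idxmax()]
        null_stats.append(null["chi2"].to_numpy())
    null_all = np.concatenate(null_stats) if null_stats else np.array([])

    order = np.argsort(obs_chi2)[::-1]
    t_sorted = obs_chi2[order]
    n_obs_ge = np.arange(1, len(t_sorted) + 1)
    null_sorted = np.sort(null_all)
    n_null_ge = len(null_all) - np.searchsorted(null_sorted, t_sorted, side="left")
    fdr = (n_null_ge / n_permutations) / n_obs_ge
    fdr = np.minimum.accumulate(fdr[::-1])[::-1]  # non-increasing in t
    fdr = np.minimum(fdr, 1.0)

    curve = pd.DataFrame({"t": t_sorted, "fdr": fdr})
    passing = np.flatnonzero(fdr <= target)
    if len(passing) == 0:
        declared = obs.iloc[0:0]
        threshold = None
        fdr_at = None
    else:
        cut = passing[-1]  # largest declared set (smallest t) meeting target
        threshold = float(t_sorted[cut])
        fdr_at = float(fdr[cut])
        declared = obs.iloc[order[: cut + 1]]
    return PluginFdrResult(n_permutations, target, threshold, fdr_at, declared, curve)


def scan_with_permutation(
    expr: ExpressionMatrix,
    geno: GenotypeMatrix,
    windows: dict[str, np.ndarray],
    covariates: tuple[str, ...] = ("disease",),
):
    """Closure for plugin_fdr: permutes expression rows AND covariate rows
    together against genotype rows, breaking genotype-expression links while
    keeping expression-covariate structure intact."""

    def closure(perm: np.ndarray) -> pd.DataFrame:
        values = expr.values.iloc[perm].set_axis(expr.values.index)
        cov = expr.covariates.iloc[perm].set_axis(expr.covariates.index)
        permuted = ExpressionMatrix(values, expr.cell_type, cov)
        return scan_cell_type(permuted, geno, windows, covariates)

    return closure


def conditional_scan(
    expr: ExpressionMatrix,
    geno: GenotypeMatrix,
    probeset: str,
    condition_snp: str,
    windows: dict[str, np.ndarray],
    covariates: tuple[str, ...] = ("disease",),
) -> pd.DataFrame:
    """Rescan one probeset with a conditioning SNP's dosage as extra covariate."""
    if condition_snp not in geno.snp_meta.index:
        raise KeyError(f"conditioning SNP {condition_snp} not in genotype data")
    j = geno.snp_meta.index.get_loc(condition_snp)
    dose = impute_missing_dosage(geno.dosage[:, [j]])[:, 0]
    x = _covariate_design(expr.covariates, covariates)
    if np.std(dose) < 1e-12:
        raise ValueError(f"conditioning SNP {condition_snp} is constant in this sample")
    q = _base_q(x)
    r = dose - q @ (q.T @ dose)
    if float(r @ r) < 1e-10 * float(dose @ dose):
        raise ValueError(f"conditioning SNP {condition_snp} collinear with covariates")
    cov = expr.covariates.copy()
    cov["_cond_dose"] = dose
    expr2 = ExpressionMatrix(expr.values[[probeset]].copy(), expr.cell_type, cov)
    sub_windows = {probeset: windows[probeset]}
    return scan_cell_type(expr2, geno, sub_windows, covariates + ("_cond_dose",))
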