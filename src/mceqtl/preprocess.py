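"""Genotype/sample QC, expression filtering and adjustment.

SNP QC applies, in a fixed order so that per-filter removal counts are
reproducible: missingness > 5% -> monomorphic -> Hardy-Weinberg exact test
(p < 1e-8) -> MAF < 5%.  Sample QC drops high-missingness samples,
heterozygosity outliers (mean +/- 3 sd) and one member of each
near-duplicate pair found by identity-by-state.  Sex-mismatch QC requires
chrX intensity data and is deliberately not implemented.

Expressed-probeset detection fits a two-component Gaussian mixture to mean
probeset expression by EM (initialized at 50/50 weights and the data's
first/third quartiles); the detection threshold is the 95th percentile of
the lower (non-expressed) component.

Expression adjustment offers two modes.  ``factor`` regresses out known
confounders then removes the top principal components of the residuals
(skipping components correlated with protected covariates) — a
deterministic latent-factor residualization.  ``batch`` equalizes per-batch
location and scale after setting aside the fit of protected covariates.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import special, stats

from mceqtl.ioformats import ExpressionMatrix, GenotypeMatrix


@dataclasses.dataclass
class QcReport:
    snp_table: pd.DataFrame | None = None
    sample_table: pd.DataFrame | None = None
    removed_counts: dict[str, int] = dataclasses.field(default_factory=dict)


def hwe_exact_test(n_het: int, n_hom_ref: int, n_hom_alt: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and enumerates all possible
    heterozygote counts with the same parity, summing the probabilities of
    tables no more likely than the observed one.  Probabilities use the
    hypergeometric-type formula

        P(het = h) = C(n, h) * C(n - h, (nA - h)/2) ... expressed via
        log-factorials for stability.
    """
    if min(n_het, n_hom_ref, n_hom_alt) < 0:
        raise ValueError("negative genotype count")
    n = n_het + n_hom_ref + n_hom_alt
    if n == 0:
        return 1.0
    n_a = 2 * n_hom_alt + n_het  # minor/alt allele count
    n_b = 2 * n_hom_ref + n_het
    if n_a > n_b:
        n_a, n_b = n_b, n_a
    if n_a == 0:
        return 1.0
    hets = np.arange(n_a % 2, n_a + 1, 2)
    hom_a = (n_a - hets) // 2
    hom_b = n - hets - hom_a
    logp = (
        hets * np.log(2.0)
        + special.gammaln(n + 1)
        - special.gammaln(hets + 1)
        - special.gammaln(hom_a + 1)
        - special.gammaln(hom_b + 1)
        + special.gammaln(n_a + 1)
        + special.gammaln(n_b + 1)
        - special.gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = probs[np.nonzero(hets == n_het)[0][0]]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


def _genotype_counts(dosage_col: np.ndarray) -> tuple[int, int, int]:
    valid = dosage_col[~np.isnan(dosage_col)]
    return (
        int((valid == 1).sum()),
        int((valid == 0).sum()),
        int((valid == 2).sum()),
    )


def qc_snps(
    geno: GenotypeMatrix,
    miss_max: float = 0.05,
    hwe_alpha: float = 1e-8,
    maf_min: float = 0.05,
) -> tuple[GenotypeMatrix, QcReport]:
    """Filter SNPs: missingness, monomorphic, HWE exact, MAF — in that order."""
    if geno.n_snps == 0:
        raise ValueError("empty genotype matrix")
    miss = geno.missing_rate()
    maf = geno.maf()
    hwe_p = np.ones(geno.n_snps)
    reason = np.array([""] * geno.n_snps, dtype=object)

    fail_miss = miss > miss_max
    reason[fail_miss] = "missingness"
    mono = (maf == 0) & ~fail_miss
    reason[mono] = "monomorphic"
    todo = ~(fail_miss | mono)
    for j in np.flatnonzero(todo):
        het, hom_ref, hom_alt = _genotype_counts(geno.dosage[:, j])
        hwe_p[j] = hwe_exact_test(het, hom_ref, hom_alt)
    fail_hwe = todo & (hwe_p < hwe_alpha)
    reason[fail_hwe] = "hwe"
    fail_maf = todo & ~fail_hwe & (maf < maf_min)
    reason[fail_maf] = "maf"

    kept = reason == ""
    table = pd.DataFrame(
        {"missing_rate": miss, "hwe_p": hwe_p, "maf": maf,
         "kept": kept, "reason": reason},
        index=geno.snp_meta.index,
    )
    counts = {
        "missingness": int(fail_miss.sum()),
        "monomorphic": int(mono.sum()),
        "hwe": int(fail_hwe.sum()),
        "maf": int(fail_maf.sum()),
    }
    report = QcReport(snp_table=table, removed_counts=counts)
    return geno.subset_snps(kept), report


def ibs_matrix(dosage: np.ndarray) -> np.ndarray:
    """Pairwise identity-by-state: mean of (2 - |g_i - g_j|)/2 over shared SNPs."""
    n = dosage.shape[0]
    out = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(dosage[i]) & ~np.isnan(dosage[j])
            if both.sum() == 0:
                out[i, j] = out[j, i] = np.nan
                continue
            sim = 1.0 - np.abs(dosage[i, both] - dosage[j, both]) / 2.0
            out[i, j] = out[j, i] = sim.mean()
    return out


def qc_samples(
    geno: GenotypeMatrix,
    miss_max: float = 0.05,
    het_sd: float = 3.0,
    ibs_max: float = 0.9,
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop samples failing missingness, heterozygosity or relatedness checks."""
    if geno.n_individuals < 3:
        raise ValueError("sample QC requires at least 3 samples")
    miss = np.mean(np.isnan(geno.dosage), axis=1)
    het = np.array([
        np.mean(geno.dosage[i][~np.isnan(geno.dosage[i])] == 1)
        for i in range(geno.n_individuals)
    ])
    reason = np.array([""] * geno.n_individuals, dtype=object)
    reason[miss > miss_max] = "missingness"

    ok = reason == ""
    mu, sd = het[ok].mean(), het[ok].std(ddof=1)
    if sd > 0:
        out_het = ok & (np.abs(het - mu) > het_sd * sd)
        reason[out_het] = "heterozygosity"

    ibs = ibs_matrix(geno.dosage)
    max_ibs = np.full(geno.n_individuals, np.nan)
    alive = np.flatnonzero(reason == "")
    for ii, i in enumerate(alive):
        others = np.delete(alive, ii)
        if len(others):
            max_ibs[i] = np.nanmax(ibs[i, others])
    # greedy: resolve the most-related pair first, dropping the noisier member
    while True:
        alive = np.flatnonzero(reason == "")
        best, pair = -np.inf, None
        for ai, i in enumerate(alive):
            for j in alive[ai + 1:]:
                if ibs[i, j] > best:
                    best, pair = ibs[i, j], (i, j)
        if pair is None or best <= ibs_max:
            break
        i, j = pair
        drop = i if (miss[i], -het[i]) >= (miss[j], -het[j]) else j
        reason[drop] = "relatedness"

    kept = reason == ""
    table = pd.DataFrame(
        {"missing_rate": miss, "heterozygosity": het, "max_ibs": max_ibs,
         "kept": kept, "reason": reason},
        index=pd.Index(geno.individual_ids, name="individual_id"),
    )
    counts = {r: int((reason == r).sum()) for r in ("missingness", "heterozygosity", "relatedness")}
    report = QcReport(sample_table=table, removed_counts=counts)
    kept_ids = [iid for iid, k in zip(geno.individual_ids, kept) if k]
    return geno.subset_individuals(kept_ids), report


def variance_filter(exprs: list[ExpressionMatrix], quantile: float = 0.75) -> set[str]:
    """Probesets whose variance is in the upper (1-quantile) tail in ANY cell type."""
    retained: set[str] = set()
    for expr in exprs:
        if expr.n_samples < 2:
            raise ValueError(f"variance undefined for single-sample matrix ({expr.cell_type})")
        var = expr.values.var(axis=0, ddof=1)
        cutoff = np.quantile(var.to_numpy(), quantile)
        retained |= set(var.index[var.to_numpy() >= cutoff])
    return retained


@dataclasses.dataclass
class MixtureFit:
    weights: tuple[float, float]       # (low, high)
    means: tuple[float, float]
    sds: tuple[float, float]
    detection_threshold: float
    converged: bool
    n_iterations: int

    def expressed(self, mean_expr: pd.Series) -> set[str]:
        return set(mean_expr.index[mean_expr > self.detection_threshold])


def fit_detection_mixture(
    mean_expr: np.ndarray | pd.Series,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> MixtureFit:
    """Two-component Gaussian EM on mean probeset expression.

    Initialized at equal weights, means at the data's quartiles, and both
    sds at the overall sd.  The lower-mean component is labeled
    non-expressed; the detection threshold is its 95th percentile,
    mu_low + z(0.95) * sigma_low.
    """
    x = np.asarray(mean_expr, dtype=float)
    if len(x) < 20:
        raise ValueError("need at least 20 values to fit the mixture")
    if not np.isfinite(x).all():
        raise ValueError("non-finite expression values")
    sd0 = x.std(ddof=1)
    if sd0 < 1e-6:
        raise ValueError("degenerate input (constant values); add jitter or check data")
    w = np.array([0.5, 0.5])
    mu = np.array([np.quantile(x, 0.25), np.quantile(x, 0.75)])
    sd = np.array([sd0, sd0])

    loglik = -np.inf
    converged = False
    for it in range(1, max_iter + 1):
        logd = np.stack([
            np.log(w[k]) + stats.norm.logpdf(x, mu[k], sd[k]) for k in range(2)
        ])
        tot = special.logsumexp(logd, axis=0)
        new_loglik = float(tot.sum())
        resp = np.exp(logd - tot)
        nk = resp.sum(axis=1)
        w = nk / len(x)
        mu = (resp @ x) / nk
        sd = np.sqrt(np.maximum((resp @ x**2) / nk - mu**2, 0.0))
        if (sd < 1e-6).any():
            raise ValueError("EM collapsed (sigma -> 0); add jitter to the input")
        if new_loglik - loglik < tol and it > 1:
            converged = True
            loglik = new_loglik
            break
        loglik = new_loglik

    order = np.argsort(mu)
    w, mu, sd = w[order], mu[order], sd[order]
    z95 = stats.norm.ppf(0.95)
    return MixtureFit(
        weights=(float(w[0]), float(w[1])),
        means=(float(mu[0]), float(mu[1])),
        sds=(float(sd[0]), float(sd[1])),
        detection_threshold=float(mu[0] + z95 * sd[0]),
        converged=converged,
        n_iterations=it,
    )


def _design(cov: pd.DataFrame, names: list[str]) -> np.ndarray:
    cols = [np.ones(len(cov))]
    for name in names:
        col = cov[name]
        if col.dtype == object or col.dtype.name == "category" or col.dtype == bool:
            dummies = pd.get_dummies(col, drop_first=True)
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy(dtype=float))
        else:
            cols.append(col.to_numpy(dtype=float))
    return np.column_stack(cols)


def _ortho_basis(x: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space of x, robust to rank deficiency."""
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    keep = s > (s[0] * 1e-10 if len(s) and s[0] > 0 else 0)
    return u[:, keep]


def _residualize(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Residuals of each column of y on the column space of x."""
    q = _ortho_basis(x)
    return y - q @ (q.T @ y)


def adjust_expression(
    expr: ExpressionMatrix,
    mode: str = "factor",
    n_factors: int = 10,
    confounders: tuple[str, ...] = ("batch", "sex"),
    protect: tuple[str, ...] = ("disease",),
    protect_corr_max: float = 0.3,
) -> ExpressionMatrix:
    """Remove unwanted expression heterogeneity.

    mode="factor": regress each probeset on the known confounders, then
    remove the top ``n_factors`` principal components of the residual
    matrix, skipping any component whose absolute correlation with a
    protected covariate exceeds ``protect_corr_max``.

    mode="batch": fit the protected covariates per probeset, equalize batch
    location and scale on the residuals, and add the protected fit back —
    batch means are removed while group differences of interest survive.
    """
    overlap = set(confounders) & set(protect)
    if overlap:
        raise ValueError(f"covariates both confounder and protected: {sorted(overlap)}")
    y = expr.values.to_numpy(dtype=float)
    cov = expr.covariates

    if mode == "factor":
        x = _design(cov, [c for c in confounders if c in cov.columns])
        resid = _residualize(y - y.mean(axis=0), x)
        if n_factors > 0:
            max_rank = min(resid.shape) - 1
            k = min(n_factors, max_rank)
            u, s_vals, vt = np.linalg.svd(resid, full_matrices=False)
            protected = [cov[p].to_numpy(dtype=float) for p in protect if p in cov.columns]
            keep_out = []
            taken = 0
            for comp in range(len(s_vals)):
                if taken >= k:
                    break
                score = u[:, comp]
                skip = False
                for pvec in protected:
                    if np.std(pvec) > 0 and abs(np.corrcoef(score, pvec)[0, 1]) > protect_corr_max:
                        skip = True
                        break
                if not skip:
                    keep_out.append(comp)
                    taken += 1
            for comp in keep_out:
                resid -= np.outer(u[:, comp] * s_vals[comp], vt[comp])
        out = resid
    elif mode == "batch":
        xp = _design(cov, [p for p in protect if p in cov.columns])
        q = _ortho_basis(xp)
        fit = q @ (q.T @ y)
        resid = y - fit
        batches = cov["batch"].to_numpy()
        pooled_sd = resid.std(axis=0, ddof=1)
        adjusted = resid.copy()
        for b in np.unique(batches):
            rows = batches == b
            sub = resid[rows]
            centered = sub - sub.mean(axis=0)
            bsd = sub.std(axis=0, ddof=1)
            scale = np.where(bsd > 1e-12, pooled_sd / np.where(bsd > 1e-12, bsd, 1.0), 1.0)
            adjusted[rows] = centered * scale
        out = adjusted + fit
    else:
        raise ValueError(f"unknown adjustment mode {mode!r}")

    values = pd.DataFrame(out, index=expr.values.index, columns=expr.values.columns)
    return expr.with_values(values)


def quantile_normal_transform(expr: ExpressionMatrix, seed: int = 0) -> ExpressionMatrix:
    """Map each probeset's values to standard-normal quantiles.

    Ranks map to Phi^{-1}((rank - 0.5)/n); ties are broken by a seeded
    random permutation, so the transform is exactly rank-based and
    invariant to any strictly monotone transformation of the input.
    """
    if expr.n_samples < 3:
        raise ValueError("need at least 3 samples")
    rng = np.random.default_rng(seed)
    y = expr.values.to_numpy(dtype=float)
    n = y.shape[0]
    out = np.empty_like(y)
    quantiles = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    for j in range(y.shape[1]):
        perm = rng.permutation(n)
        order = perm[np.argsort(y[perm, j], kind="stable")]
        ranks = np.empty(n, dtype=int)
        ranks[order] = np.arange(n)
        out[:, j] = quantiles[ranks]
    values = pd.DataFrame(out, index=expr.values.index, columns=expr.values.columns)
    return expr.with_values(values)
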