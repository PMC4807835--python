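"""Joint Bayesian model averaging over eQTL configurations across subgroups.

For S subgroups (cell types or timepoints) there are 2^S - 1 non-null
configurations of eQTL presence/absence.  Per (gene, SNP) pair and
configuration, an approximate Bayes factor is computed from per-subgroup
OLS summaries (beta_hat, se) under the effect decomposition

    b_s = b_bar + e_s,   b_bar ~ N(0, omega^2),   e_s ~ N(0, phi^2)

for active subgroups, averaged over a grid of (phi^2, omega^2) values.
Errors are treated as independent across subgroups (the overlapping-
individual correlation is ignored; see docs).  The marginal likelihood
ratio is available in closed form because the alternative covariance is
diag(V_s) + phi^2 I + omega^2 J: a rank-one update of a diagonal.

A hierarchical model with hyperparameters pi0 (probability of no eQTL in
any subgroup) and eta (configuration probabilities) is fitted by EM over
the per-gene mixture likelihood

    L_g = pi0 + (1 - pi0) * (1/m_g) * sum_snp sum_gamma eta_gamma * BF,

with a uniform SNP prior over the gene's m_g cis SNPs.  Posteriors follow:
PP(gene has an eQTL), PP(SNP is "the" eQTL | eQTL), PP(configuration) at
the best SNP, per-subgroup activity PPs, the MAP configuration, and the
Shannon entropy of the configuration posterior.  Significance uses the
Bayes FDR: declare the largest PP-ranked prefix whose mean (1 - PP) stays
below the target.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd
from scipy import special

from mceqtl.cis_scan import scan_cell_type
from mceqtl.ioformats import ExpressionMatrix, GenotypeMatrix, align_samples


def enumerate_configurations(n_subgroups: int) -> np.ndarray:
    """All 2^S - 1 non-null presence/absence vectors, ordered by
    (number active, lexicographic) so ties resolve toward sparser configs."""
    if not 1 <= n_subgroups <= 16:
        raise ValueError("n_subgroups must be in 1..16")
    configs = [
        np.array(bits, dtype=bool)
        for bits in itertools.product([0, 1], repeat=n_subgroups)
        if any(bits)
    ]
    configs.sort(key=lambda c: (int(c.sum()), tuple(~c)))
    return np.array(configs)


def config_label(config: np.ndarray) -> str:
    return "".join("1" if b else "0" for b in config)


@dataclasses.dataclass(frozen=True)
class Grid:
    """Effect-size prior grid: rows of (phi^2, omega^2) with weights lam."""

    phi2: np.ndarray
    omega2: np.ndarray
    lam: np.ndarray

    def __post_init__(self) -> None:
        if (self.phi2 < 0).any() or (self.omega2 < 0).any():
            raise ValueError("variances must be non-negative")
        if ((self.phi2 + self.omega2) <= 0).any():
            raise ValueError("phi^2 + omega^2 must be positive")
        if abs(self.lam.sum() - 1.0) > 1e-8:
            raise ValueError("grid weights must sum to 1")


def default_grid(
    total_variances: tuple[float, ...] = (0.01, 0.04, 0.16, 0.64, 2.56),
    heterogeneity_fractions: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0),
) -> Grid:
    phi2, omega2 = [], []
    for w in total_variances:
        for h in heterogeneity_fractions:
            phi2.append(h * w)
            omega2.append((1.0 - h) * w)
    k = len(phi2)
    return Grid(np.array(phi2), np.array(omega2), np.full(k, 1.0 / k))


def log_abf_single(beta_hat: float, se: float, prior_var: float) -> float:
    """Log approximate Bayes factor for one subgroup under prior N(0, W)."""
    if se <= 0:
        raise ValueError("se must be positive")
    if prior_var < 0:
        raise ValueError("prior variance must be non-negative")
    v = se**2
    z2 = (beta_hat / se) ** 2
    shrink = prior_var / (v + prior_var)
    return 0.5 * np.log(v / (v + prior_var)) + 0.5 * z2 * shrink


def abf_single(beta_hat: float, se: float, prior_var: float) -> float:
    return float(np.exp(log_abf_single(beta_hat, se, prior_var)))


@dataclasses.dataclass
class SubgroupSummaries:
    """Per (gene, SNP, subgroup) OLS effect summaries.

    ``pairs`` carries probeset/snp; ``beta_hat`` and ``se`` are P x S with
    NaN where a pair is unavailable in a subgroup.
    """

    pairs: pd.DataFrame
    beta_hat: np.ndarray
    se: np.ndarray
    subgroups: list[str]


def subgroup_summaries(
    exprs: list[ExpressionMatrix],
    geno: GenotypeMatrix,
    windows: dict[str, np.ndarray],
    covariates: tuple[str, ...] = ("disease",),
    min_samples: int = 10,
) -> SubgroupSummaries:
    """OLS (beta_hat, se) per (gene, SNP) in every subgroup.

    Each subgroup is aligned to the genotype matrix separately, so
    subgroups may cover different (overlapping) individual subsets.
    Expression is expected to be quantile-normal transformed already.
    """
    frames = []
    labels = []
    for expr in exprs:
        if expr.n_samples < min_samples:
            raise ValueError(
                f"subgroup {expr.cell_type} has {expr.n_samples} samples (< {min_samples})"
            )
        g_sub, e_sub, _ = align_samples(geno, expr)
        rec = scan_cell_type(e_sub, g_sub, windows, covariates)
        frames.append(rec.set_index(["probeset", "snp"])[["beta", "se"]])
        labels.append(expr.cell_type)
    pairs_index = frames[0].index
    for f in frames[1:]:
        pairs_index = pairs_index.union(f.index)
    p = len(pairs_index)
    s = len(frames)
    beta_hat = np.full((p, s), np.nan)
    se = np.full((p, s), np.nan)
    for k, f in enumerate(frames):
        f = f.reindex(pairs_index)
        beta_hat[:, k] = f["beta"].to_numpy()
        se[:, k] = f["se"].to_numpy()
    pairs = pairs_index.to_frame(index=False)
    return SubgroupSummaries(pairs, beta_hat, se, labels)


def config_log_bfs(
    summaries: SubgroupSummaries,
    grid: Grid | None = None,
    configs: np.ndarray | None = None,
    per_grid_point: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Grid-averaged log Bayes factors for every (pair, configuration).

    Returns (log_bf [P x C], configs [C x S]); with ``per_grid_point`` the
    first element is instead the raw [K x P x C] array of per-grid-point
    log BFs (no lambda averaging), for EMs that update the grid weights.
    Pairs missing in a subgroup contribute a factor of 1 for that subgroup
    (no data, no evidence).
    """
    if grid is None:
        grid = default_grid()
    s = len(summaries.subgroups)
    if configs is None:
        configs = enumerate_configurations(s)
    beta = summaries.beta_hat
    v = summaries.se**2
    present = np.isfinite(beta) & np.isfinite(v) & (v > 0)
    beta = np.where(present, beta, 0.0)
    v = np.where(present, v, 1.0)

    p = beta.shape[0]
    n_grid = len(grid.lam)
    c = configs.shape[0]
    log_bf_grid = np.empty((n_grid, p, c))
    cfg_f = configs.T.astype(float)  # S x C
    for gi in range(n_grid):
        phi2, omega2 = grid.phi2[gi], grid.omega2[gi]
        a = v + phi2
        # per-subgroup contributions, zeroed where data absent
        dlog = np.where(present, np.log(a) - np.log(v), 0.0)
        inva = np.where(present, 1.0 / a, 0.0)
        dquad = np.where(present, beta**2 / v - beta**2 / a, 0.0)
        ba = np.where(present, beta / a, 0.0)
        # sum over active subgroups for every configuration: P x C
        s_dlog = dlog @ cfg_f
        s_inva = inva @ cfg_f
        s_dquad = dquad @ cfg_f
        s_ba = ba @ cfg_f
        denom = 1.0 + omega2 * s_inva
        log_bf_grid[gi] = (
            -0.5 * s_dlog
            - 0.5 * np.log(denom)
            + 0.5 * (s_dquad + omega2 * s_ba**2 / denom)
        )
    if per_grid_point:
        return log_bf_grid, configs
    log_bf = special.logsumexp(
        log_bf_grid + np.log(grid.lam)[:, None, None], axis=0
    )
    return log_bf, configs


@dataclasses.dataclass
class HyperParams:
    pi0: float
    eta: np.ndarray           # over configurations, sums to 1
    configs: np.ndarray       # C x S
    log_likelihood: float
    n_iterations: int
    converged: bool
    loglik_trace: np.ndarray | None = None
    lam: np.ndarray | None = None   # fitted grid weights (None = fixed)


def _gene_groups(pairs: pd.DataFrame) -> tuple[list[str], list[np.ndarray]]:
    genes = pairs["probeset"].to_numpy()
    order = np.argsort(genes, kind="stable")
    uniq, starts = np.unique(genes[order], return_index=True)
    groups = np.split(order, starts[1:])
    return list(uniq), groups


def fit_hierarchical_em(
    log_bf: np.ndarray,
    configs: np.ndarray,
    pairs: pd.DataFrame,
    tol: float = 1e-6,
    max_iter: int = 1000,
    update_lambda: bool = False,
) -> HyperParams:
    """Maximum-likelihood (pi0, eta[, lambda]) by EM over the per-gene mixture.

    ``log_bf`` is either [P x C] (grid already averaged, lambda fixed) or
    [K x P x C] per-grid-point (requires ``update_lambda``), in which case
    the grid weights lambda are estimated as additional mixture weights.
    The log-likelihood is non-decreasing every iteration; convergence when
    the increase drops below ``tol``.
    """
    if not np.isfinite(log_bf).all():
        bad = np.argwhere(~np.isfinite(log_bf))[0]
        raise ValueError(f"non-finite Bayes factor at array index {tuple(bad)}")
    if update_lambda and log_bf.ndim != 3:
        raise ValueError("lambda update needs per-grid-point [K x P x C] BFs")
    if log_bf.ndim == 2:
        log_bf = log_bf[None, :, :]
    k, _, c = log_bf.shape

    genes, groups = _gene_groups(pairs)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes to fit hyperparameters")
    pi0 = 0.5
    log_eta = np.full(c, -np.log(c))
    log_lam = np.full(k, -np.log(k))

    # rows grouped contiguously by gene, SNP prior 1/m_g folded in
    order = np.concatenate(groups)
    sizes = np.array([len(g) for g in groups])
    starts = np.r_[0, np.cumsum(sizes)[:-1]]
    row_gene = np.repeat(np.arange(len(genes)), sizes)
    lbf = np.moveaxis(log_bf[:, order, :], 0, 1).reshape(len(order), k * c)
    lbf = lbf - np.log(sizes)[row_gene, None]

    trace = []
    prev = -np.inf
    converged = False
    for it in range(1, max_iter + 1):
        log_w = (log_lam[:, None] + log_eta[None, :]).ravel()  # K*C
        a = lbf + log_w[None, :]
        pair_max = a.max(axis=1)
        exp_a = np.exp(a - pair_max[:, None])
        pair_sum = exp_a.sum(axis=1)
        log_pair = pair_max + np.log(pair_sum)
        seg_max = np.maximum.reduceat(log_pair, starts)
        log_bbar = seg_max + np.log(
            np.add.reduceat(np.exp(log_pair - seg_max[row_gene]), starts)
        )
        log_alt = np.log1p(-pi0) + log_bbar if pi0 < 1 else np.full_like(log_bbar, -np.inf)
        log_null = np.log(pi0) if pi0 > 0 else -np.inf
        log_l = np.logaddexp(log_null, log_alt)
        loglik = float(log_l.sum())
        trace.append(loglik)
        z = np.exp(log_alt - log_l)  # P(gene has an eQTL | data)

        # responsibility mass per (grid point, config), pooled over genes
        pair_w = z[row_gene] * np.exp(log_pair - log_bbar[row_gene])
        acc = ((pair_w / pair_sum)[:, None] * exp_a).sum(axis=0).reshape(k, c)
        eta_acc = acc.sum(axis=0)
        lam_acc = acc.sum(axis=1)
        if loglik - prev < tol and it > 1:
            converged = True
            break
        prev = loglik
        pi0 = float(np.clip(1.0 - z.mean(), 1e-12, 1.0 - 1e-12))
        if eta_acc.sum() > 0:
            log_eta = np.log(np.clip(eta_acc / eta_acc.sum(), 1e-300, None))
        else:
            log_eta = np.full(c, -np.log(c))
        if update_lambda and lam_acc.sum() > 0:
            log_lam = np.log(np.clip(lam_acc / lam_acc.sum(), 1e-300, None))

    if np.allclose(np.exp(log_bf), 1.0):
        import warnings

        warnings.warn("all Bayes factors are 1: likelihood flat in pi0; reporting pi0=1")
        pi0 = 1.0
    return HyperParams(
        pi0=pi0,
        eta=np.exp(log_eta),
        configs=configs,
        log_likelihood=trace[-1],
        n_iterations=it,
        converged=converged,
        loglik_trace=np.array(trace),
        lam=np.exp(log_lam) if update_lambda else None,
    )


def pi0_ebf_plugin(log_bf: np.ndarray, configs: np.ndarray, pairs: pd.DataFrame) -> float:
    """Alternative pi0 estimate: fraction of genes whose gene-level BF
    (uniform eta, uniform SNP prior) does not exceed 1."""
    _, groups = _gene_groups(pairs)
    c = configs.shape[0]
    log_bbar = np.array([
        special.logsumexp(log_bf[rows]) - np.log(len(rows)) - np.log(c)
        for rows in groups
    ])
    return float(np.mean(log_bbar <= 0.0))


@dataclasses.dataclass
class BmaGeneResult:
    probeset: str
    best_snp: str
    log_bf_gene: float
    pp_gene: float
    pp_snp: pd.Series                 # over cis SNPs
    pp_config: np.ndarray             # over configurations, at best SNP
    map_config: str
    activity_pp: dict[str, float]     # per-subgroup P(active)
    entropy: float


def posteriors(
    log_bf: np.ndarray,
    configs: np.ndarray,
    pairs: pd.DataFrame,
    hp: HyperParams,
    subgroups: list[str],
) -> list[BmaGeneResult]:
    """Posterior summaries per gene under fitted hyperparameters."""
    genes, groups = _gene_groups(pairs)
    log_eta = np.log(np.clip(hp.eta, 1e-300, None))
    results = []
    snps_all = pairs["snp"].to_numpy()
    for gname, rows in zip(genes, groups):
        lbf = log_bf[rows]
        m = len(rows)
        lw = lbf + log_eta[None, :]             # m x C
        log_snp = special.logsumexp(lw, axis=1)  # per-SNP marginal
        log_bbar = special.logsumexp(log_snp) - np.log(m)
        if hp.pi0 >= 1.0:
            pp_gene = 0.0
        else:
            log_odds = np.log1p(-hp.pi0) - np.log(hp.pi0) + log_bbar if hp.pi0 > 0 else np.inf
            pp_gene = 1.0 if np.isinf(log_odds) else float(special.expit(log_odds))
        pp_snp = np.exp(log_snp - special.logsumexp(log_snp))
        best_local = int(np.argmax(pp_snp))
        lw_best = lw[best_local]
        pp_config = np.exp(lw_best - special.logsumexp(lw_best))
        map_idx = int(np.argmax(pp_config))  # argmax; config order favors sparser on ties
        activity = {
            sg: float(pp_config[configs[:, si]].sum())
            for si, sg in enumerate(subgroups)
        }
        nz = pp_config[pp_config > 0]
        entropy = float(-(nz * np.log2(nz)).sum())
        results.append(
            BmaGeneResult(
                probeset=gname,
                best_snp=str(snps_all[rows[best_local]]),
                log_bf_gene=float(log_bbar),
                pp_gene=pp_gene,
                pp_snp=pd.Series(pp_snp, index=snps_all[rows]),
                pp_config=pp_config,
                map_config=config_label(configs[map_idx]),
                activity_pp=activity,
                entropy=entropy,
            )
        )
    return results


def bayes_fdr(results: list[BmaGeneResult], target: float = 0.05) -> set[str]:
    """Largest PP-ranked prefix with mean(1 - PP_gene) <= target."""
    if not results:
        return set()
    order = sorted(results, key=lambda r: -r.pp_gene)
    pps = np.array([r.pp_gene for r in order])
    mean_fdr = np.cumsum(1.0 - pps) / np.arange(1, len(pps) + 1)
    passing = np.flatnonzero(mean_fdr <= target)
    if len(passing) == 0:
        return set()
    k = passing[-1] + 1
    return {r.probeset for r in order[:k]}


def results_table(results: list[BmaGeneResult], subgroups: list[str]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "probeset": r.probeset,
            "best_snp": r.best_snp,
            "pp_gene": r.pp_gene,
            "map_config": r.map_config,
            "pp_config_max": float(r.pp_config.max()),
            "entropy": r.entropy,
        }
        for sg in subgroups:
            row[f"activity_pp_{sg}"] = r.activity_pp[sg]
        rows.append(row)
    return pd.DataFrame(rows).set_index("probeset")


def run_bma(
    exprs: list[ExpressionMatrix],
    geno: GenotypeMatrix,
    windows: dict[str, np.ndarray],
    covariates: tuple[str, ...] = ("disease",),
    grid: Grid | None = None,
    fdr_target: float = 0.05,
) -> tuple[list[BmaGeneResult], HyperParams, set[str]]:
    """Full joint analysis: summaries -> BFs -> EM -> posteriors -> Bayes FDR.

    Grid weights lambda are fitted by the EM alongside (pi0, eta);
    posteriors use the fitted weights.
    """
    summ = subgroup_summaries(exprs, geno, windows, covariates)
    log_bf_grid, configs = config_log_bfs(summ, grid, per_grid_point=True)
    hp = fit_hierarchical_em(log_bf_grid, configs, summ.pairs, update_lambda=True)
    log_bf = special.logsumexp(
        log_bf_grid + np.log(np.clip(hp.lam, 1e-300, None))[:, None, None], axis=0
    )
    res = posteriors(log_bf, configs, summ.pairs, hp, summ.subgroups)
    declared = bayes_fdr(res, fdr_target)
    return res, hp, declared


def permutation_negative_control(
    exprs: list[ExpressionMatrix],
    geno: GenotypeMatrix,
    windows: dict[str, np.ndarray],
    permute_subgroup: str,
    seed: int = 0,
    covariates: tuple[str, ...] = ("disease",),
    grid: Grid | None = None,
    fdr_target: float = 0.05,
):
    """Re-run the joint analysis with one subgroup's sample labels permuted.

    Only the named subgroup's expression rows are shuffled against its
    individual ids; genotype and the other subgroups are untouched.
    """
    labels = [e.cell_type for e in exprs]
    if permute_subgroup not in labels:
        raise KeyError(f"unknown subgroup {permute_subgroup}")
    rng = np.random.default_rng(seed)
    permuted = []
    for e in exprs:
        if e.cell_type == permute_subgroup:
            perm = rng.permutation(e.n_samples)
            values = e.values.iloc[perm].set_axis(e.values.index)
            permuted.append(ExpressionMatrix(values, e.cell_type, e.covariates.copy()))
        else:
            permuted.append(e)
    return run_bma(permuted, geno, windows, covariates, grid, fdr_target)
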