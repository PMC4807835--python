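"""Two-step genotype x disease interaction eQTL scan.

Step 1 screens (gene, cis SNP) pairs by the genotype main effect from a
regression of expression on genotype WITH NO COVARIATES — in particular
without disease status, which makes the step-1 statistic independent of
the step-2 interaction statistic and so keeps the step-2 FDR honest.  Only
pairs with main-effect p below alpha1 survive, and only the single most
significant SNP per gene goes forward.  SNPs are restricted to MAF >= 10%.

Step 2 fits the full interaction model by OLS,

    y = b0 + bg * g + bd * d + bgd * (g * d) + eps,

tests bgd with a two-sided t-test, adjusts over exactly the number of
step-2 tests with Benjamini-Hochberg (15% FDR threshold), and also reports
Storey q-values.

Expression should be batch-adjusted (location/scale mode, disease
preserved) but NOT quantile-transformed, so interaction effect sizes stay
on the expression scale.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import interpolate, stats
from statsmodels.stats.multitest import multipletests

from mceqtl.cis_scan import _scan_arrays
from mceqtl.ioformats import ExpressionMatrix, GenotypeMatrix, impute_missing_dosage


def step1_filter(
    expr: ExpressionMatrix,
    geno: GenotypeMatrix,
    windows: dict[str, np.ndarray],
    alpha1: float = 5e-5,
    maf_min: float = 0.10,
) -> pd.DataFrame:
    """Candidate (probeset, snp) pairs: per gene, the most significant SNP
    among those with intercept-only main-effect p < alpha1."""
    if expr.n_samples != geno.n_individuals:
        raise ValueError("expression and genotype matrices are not aligned")
    maf_ok = geno.maf() >= maf_min
    windows_f = {
        ps: idx[maf_ok[idx]] for ps, idx in windows.items()
    }
    y_mat = expr.values.to_numpy(dtype=float)
    dosage = impute_missing_dosage(geno.dosage)
    x = np.ones((expr.n_samples, 1))
    probesets = list(expr.probeset_ids)
    chi2, _, _, pairs = _scan_arrays(y_mat, dosage, x, windows_f, probesets)
    if not pairs:
        return pd.DataFrame(columns=["probeset", "snp", "step1_p"])
    p_vals = stats.chi2.sf(chi2, df=1)
    snp_ids = geno.snp_meta.index.to_numpy()
    df = pd.DataFrame(
        {
            "probeset": [probesets[i] for i, _ in pairs],
            "snp": [snp_ids[j] for _, j in pairs],
            "step1_p": p_vals,
        }
    ).dropna(subset=["step1_p"])
    df = df[df["step1_p"] < alpha1]
    if df.empty:
        return df.reset_index(drop=True)
    best = df.loc[df.groupby("probeset")["step1_p"].idxmin()]
    return best.sort_values("probeset").reset_index(drop=True)


def storey_qvalues(p: np.ndarray, lambdas: np.ndarray | None = None) -> tuple[np.ndarray, float]:
    """Storey q-values with spline-smoothed pi0 over lambda = 0.05..0.95."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    if m == 0:
        return p.copy(), 1.0
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    if m < 20 or p.min() == p.max():
        pi0 = 1.0
    else:
        pi0_l = np.array([np.mean(p > lam) / (1.0 - lam) for lam in lambdas])
        try:
            spline = interpolate.UnivariateSpline(lambdas, pi0_l, k=3)
            pi0 = float(spline(lambdas[-1]))
        except Exception:
            pi0 = float(pi0_l[-1])
        pi0 = float(np.clip(pi0, 1e-8, 1.0))
    order = np.argsort(p)
    q = np.empty(m)
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q[order] = np.minimum.accumulate(ranked[::-1])[::-1]
    return np.minimum(q, 1.0), pi0


@dataclasses.dataclass
class InteractionScanResult:
    records: pd.DataFrame          # one row per tested candidate
    n_tested: int                  # BH universe size
    n_excluded: int                # candidates dropped for unstable cells
    declared: pd.DataFrame         # records with p_int_bh <= fdr
    pi0: float


def step2_interaction(
    candidates: pd.DataFrame,
    expr: ExpressionMatrix,
    geno: GenotypeMatrix,
    fdr: float = 0.15,
) -> InteractionScanResult:
    """Full-model OLS fit and interaction test for each step-1 candidate."""
    d = expr.covariates["disease"].to_numpy(dtype=float)
    if len(np.unique(d)) < 2:
        raise ValueError("no disease variation in this dataset")
    y_all = expr.values
    dosage = impute_missing_dosage(geno.dosage)
    snp_pos = {s: i for i, s in enumerate(geno.snp_meta.index)}

    rows, excluded = [], 0
    for _, cand in candidates.iterrows():
        g = dosage[:, snp_pos[cand["snp"]]]
        # both disease strata need >= 2 distinct genotype values
        stable = all(len(np.unique(np.round(g[d == grp]))) >= 2 for grp in (0.0, 1.0))
        if not stable:
            excluded += 1
            continue
        y = y_all[cand["probeset"]].to_numpy(dtype=float)
        x = np.column_stack([np.ones_like(g), g, d, g * d])
        coef, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ coef
        dof = len(y) - 4
        sigma2 = float(resid @ resid) / dof
        cov = sigma2 * np.linalg.inv(x.T @ x)
        se = np.sqrt(np.diag(cov))
        t_gd = coef[3] / se[3]
        p_int = 2.0 * stats.t.sf(abs(t_gd), dof)
        rows.append(
            {
                "probeset": cand["probeset"],
                "snp": cand["snp"],
                "cell_type": expr.cell_type,
                "step1_p": cand.get("step1_p", np.nan),
                "beta0": coef[0], "beta_g": coef[1],
                "beta_d": coef[2], "beta_gd": coef[3],
                "se_gd": se[3], "p_int": p_int,
            }
        )
    records = pd.DataFrame(rows)
    if records.empty:
        return InteractionScanResult(records, 0, excluded, records, 1.0)
    _, bh, _, _ = multipletests(records["p_int"].to_numpy(), method="fdr_bh")
    records["p_int_bh"] = bh
    records["p_int_bonf"] = np.minimum(records["p_int"] * len(records), 1.0)
    q, pi0 = storey_qvalues(records["p_int"].to_numpy())
    records["q_value"] = q
    declared = records[records["p_int_bh"] <= fdr].reset_index(drop=True)
    return InteractionScanResult(records, len(records), excluded, declared, pi0)


def two_step_scan(
    expr: ExpressionMatrix,
    geno: GenotypeMatrix,
    windows: dict[str, np.ndarray],
    alpha1: float = 5e-5,
    maf_min: float = 0.10,
    fdr: float = 0.15,
) -> InteractionScanResult:
    """Convenience wrapper: step-1 filter then step-2 interaction test."""
    candidates = step1_filter(expr, geno, windows, alpha1, maf_min)
    return step2_interaction(candidates, expr, geno, fdr)
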